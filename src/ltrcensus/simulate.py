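"""Synthetic genomes with planted LTR-retrotransposon content.

Generates element blueprints organised as superfamily -> clade -> family
trees of sequence divergence, plants mutated copies (full, truncated,
solo-LTR, nested) into random background contigs, and records every plant
in a TruthSet that downstream stages are scored against. Everything is
driven by a single integer seed and is byte-reproducible.

The generator emulates the copy-degradation states a library-based genome
scan recovers but a structural (paired-LTR) detector cannot: truncated
copies, solo LTRs left by inter-LTR recombination, and copies corrupted by
nested insertions of other elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import PanelEntry, ReferencePanel
from .io import revcomp

SUPERFAMILIES = ("Gypsy", "Copia", "BELPao")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


class PlacementError(RuntimeError):
    """Raised when a copy cannot be placed without violating spacing rules."""


class GeometryError(ValueError):
    """Raised when blueprint geometry cannot satisfy the detection window."""


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def random_cds(n_aa: int, rng: np.random.Generator) -> str:
    """Random coding sequence of n_aa codons with no stop codons."""
    out = []
    while len(out) < n_aa:
        codon = rng.choice(_BASES, size=3).tobytes().decode()
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def translate(nt: str) -> str:
    return str(Seq(nt[: 3 * (len(nt) // 3)]).translate())


# ---------------------------------------------------------------------------
# Mutation model


def mutate_sequence(seq: str, sub_rate: float, indel_rate: float = 0.0,
                    mean_indel_len: float = 3.0, seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    return_script: bool = False,
                    protect_frame: tuple[int, int] | None = None):
    """Apply i.i.d. substitutions and geometric-length indels to ``seq``.

    Substitutions always change the base. Indel events are drawn per site;
    insertions and deletions are equiprobable and lengths are geometric
    with the given mean. With ``return_script`` the realised edit script is
    returned as a list of (position, op, payload) tuples (op in
    {"sub", "ins", "del"}). Zero rates return the input unchanged.

    ``protect_frame`` marks a half-open interval treated as coding: indels
    are suppressed inside it and substitutions that would create an
    in-frame stop codon (frame anchored at the interval start) are
    redrawn or skipped.
    """
    if not seq:
        raise ValueError("sequence is empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    script: list[tuple[int, str, str]] = []
    chars = list(seq)
    n = len(chars)

    if sub_rate > 0:
        positions = np.flatnonzero(rng.random(n) < sub_rate)
        for pos in positions:
            old = chars[pos]
            choices = [b for b in "ACGT" if b != old]
            new = choices[int(rng.integers(3))]
            if protect_frame and protect_frame[0] <= pos < protect_frame[1]:
                new = _safe_sub(chars, int(pos), choices, protect_frame, rng)
                if new is None:
                    continue
            chars[pos] = new
            script.append((int(pos), "sub", new))

    if indel_rate > 0:
        events = np.flatnonzero(rng.random(n) < indel_rate)
        p_geo = min(1.0, 1.0 / max(mean_indel_len, 1.0))
        # apply right-to-left so earlier positions stay valid
        for pos in events[::-1]:
            pos = int(pos)
            if protect_frame and protect_frame[0] <= pos < protect_frame[1]:
                continue
            length = int(rng.geometric(p_geo))
            if rng.random() < 0.5:
                ins = random_dna(length, rng)
                chars[pos:pos] = list(ins)
                script.append((pos, "ins", ins))
            else:
                deleted = "".join(chars[pos : pos + length])
                del chars[pos : pos + length]
                script.append((pos, "del", deleted))

    out = "".join(chars)
    if return_script:
        return out, script
    return out


def _safe_sub(chars: list[str], pos: int, choices: list[str],
              frame: tuple[int, int], rng: np.random.Generator) -> str | None:
    """Pick a replacement base that keeps the codon at ``pos`` stop-free."""
    start = frame[0]
    codon_start = start + 3 * ((pos - start) // 3)
    order = list(rng.permutation(choices))
    for cand in order:
        codon = list(chars[codon_start : codon_start + 3])
        if len(codon) < 3:
            return cand
        codon[pos - codon_start] = cand
        if "".join(codon) not in _STOPS:
            return cand
    return None


# ---------------------------------------------------------------------------
# Element library


@dataclass(frozen=True)
class ElementBlueprint:
    """A family's reference element: two identical LTRs around an internal
    region that carries an RT/RNaseH coding stretch.

    Copia elements carry the integrase upstream of RT (domain block early
    in *pol*), Gypsy and BEL/Pao downstream of RNaseH; here that surfaces
    as the offset of the RT/RNaseH coding stretch inside the internal
    region.
    """

    family_id: str
    clade_id: str
    superfamily: str
    species: str
    ltr_seq: str
    internal_seq: str
    cds_span: tuple[int, int]  # within internal_seq, half-open, multiple of 3

    def __post_init__(self):
        if not 80 <= len(self.ltr_seq) <= 1500:
            raise GeometryError(f"{self.family_id}: LTR length {len(self.ltr_seq)} outside [80, 1500]")
        dist = len(self.ltr_seq) + len(self.internal_seq)  # start-to-start inter-LTR distance
        if not 2500 <= dist <= 11000:
            raise GeometryError(f"{self.family_id}: inter-LTR distance {dist} outside [2500, 11000]")
        aa_len = (self.cds_span[1] - self.cds_span[0]) // 3
        if aa_len < 150:
            raise GeometryError(f"{self.family_id}: RT/RNaseH {aa_len} aa < 150")
        if "*" in self.domain_aa:
            raise GeometryError(f"{self.family_id}: internal stop codon in RT/RNaseH")

    @property
    def integrase_position(self) -> str:
        return "upstream_of_RT" if self.superfamily == "Copia" else "downstream_of_RNaseH"

    @property
    def element_seq(self) -> str:
        return self.ltr_seq + self.internal_seq + self.ltr_seq

    @property
    def cds_nt(self) -> str:
        return self.internal_seq[self.cds_span[0] : self.cds_span[1]]

    @property
    def domain_aa(self) -> str:
        return translate(self.cds_nt)

    @property
    def ltr_len(self) -> int:
        return len(self.ltr_seq)


def build_element_library(n_clades: int, families_per_clade: int,
                          clade_divergence: float, family_divergence: float,
                          seed: int, *, ltr_len: int = 300, internal_len: int = 4200,
                          domain_aa_len: int = 300,
                          species: Sequence[str] = ("SpA",),
                          refs_per_clade: int = 3, ref_divergence: float = 0.10,
                          superfamilies: Sequence[str] = SUPERFAMILIES,
                          ) -> tuple[list[ElementBlueprint], ReferencePanel]:
    """Simulate a library of family blueprints plus a labelled reference panel.

    Clades cycle over the three superfamilies. Within a superfamily all
    clades descend from one ancestral element; clade ancestors diverge
    from it at ``clade_divergence`` substitutions/site and families from
    their clade ancestor at ``family_divergence``, so within-clade
    similarity exceeds between-clade similarity in expectation. Families
    are assigned to ``species`` round-robin within each clade. The panel
    carries ``refs_per_clade`` labelled RT/RNaseH amino-acid references
    per clade, mutated from the clade ancestor at ``ref_divergence``.
    """
    if n_clades < 1 or families_per_clade < 1:
        raise ValueError("counts must be >= 1")
    for d in (clade_divergence, family_divergence):
        if not 0 <= d <= 0.6:
            raise ValueError("divergence must lie in [0, 0.6]")
    if internal_len < 3 * domain_aa_len + 200:
        raise GeometryError("internal region too short to host the RT/RNaseH coding stretch")
    rng = np.random.default_rng(seed)

    # per-superfamily ancestral parts
    roots: dict[str, tuple[str, str, str]] = {}
    for sf in superfamilies:
        root_ltr = random_dna(ltr_len, rng)
        root_cds = random_cds(domain_aa_len, rng)
        root_internal = random_dna(internal_len - len(root_cds), rng)
        roots[sf] = (root_ltr, root_cds, root_internal)

    blueprints: list[ElementBlueprint] = []
    panel_entries: list[PanelEntry] = []
    for ci in range(n_clades):
        sf = superfamilies[ci % len(superfamilies)]
        clade_id = f"{sf}-clade{ci + 1}"
        root_ltr, root_cds, root_internal = roots[sf]
        clade_ltr = mutate_sequence(root_ltr, clade_divergence, rng=rng)
        clade_cds = mutate_sequence(root_cds, clade_divergence, rng=rng,
                                    protect_frame=(0, len(root_cds)))
        clade_internal = mutate_sequence(root_internal, clade_divergence, rng=rng)
        # Copia: domain early in pol (integrase upstream of RT) -> small offset;
        # Gypsy/BEL-Pao: domain late -> larger offset.
        offset = 100 if sf == "Copia" else max(len(clade_internal) - len(clade_cds) - 100, 100)
        for fi in range(families_per_clade):
            fam_ltr = mutate_sequence(clade_ltr, family_divergence, rng=rng)
            fam_cds = mutate_sequence(clade_cds, family_divergence, rng=rng,
                                      protect_frame=(0, len(clade_cds)))
            fam_internal = mutate_sequence(clade_internal, family_divergence, rng=rng)
            internal = fam_internal[:offset] + fam_cds + fam_internal[offset:]
            sp = species[fi % len(species)]
            fid = f"{sf}-{ci + 1}.{fi + 1}_{sp}"
            blueprints.append(ElementBlueprint(
                family_id=fid, clade_id=clade_id, superfamily=sf, species=sp,
                ltr_seq=fam_ltr, internal_seq=internal,
                cds_span=(offset, offset + len(fam_cds))))
        for ri in range(refs_per_clade):
            ref_cds = clade_cds if ri == 0 else mutate_sequence(
                clade_cds, ref_divergence, rng=rng, protect_frame=(0, len(clade_cds)))
            panel_entries.append(PanelEntry(
                entry_id=f"{clade_id}_ref{ri + 1}", aa_seq=translate(ref_cds),
                superfamily=sf, clade=clade_id))
    return blueprints, ReferencePanel(panel_entries)


# ---------------------------------------------------------------------------
# Planting


@dataclass(frozen=True)
class PlantSpec:
    """Conditions of a simulation run; all randomness flows from ``seed``."""

    n_contigs: int = 2
    contig_length: int = 500_000
    copies_per_family: int | tuple[int, int] | Mapping[str, int] = 5
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    mean_indel_len: float = 3.0
    truncation_prob: float = 0.0
    solo_ltr_prob: float = 0.0
    nesting_prob: float = 0.0
    minus_strand_prob: float = 0.5
    min_spacing: int = 2000
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("sub_rate", "indel_rate", "truncation_prob", "solo_ltr_prob",
                     "nesting_prob", "minus_strand_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class TruthRecord:
    contig: str
    start: int
    end: int
    strand: str
    family_id: str
    clade_id: str
    superfamily: str
    state: str  # full | truncated | solo_ltr | nested_host
    ltr_len: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("zero- or negative-length truth record")


@dataclass
class TruthSet:
    """Ledger of planted copies; the oracle downstream stages are scored on."""

    records: list[TruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def by_state(self, state: str) -> list[TruthRecord]:
        return [r for r in self.records if r.state == state]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.records])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tstart\tend\tstrand\tfamily_id\tclade_id\tsuperfamily\tstate\tltr_len\n")
            for r in self.records:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.strand}\t{r.family_id}\t"
                         f"{r.clade_id}\t{r.superfamily}\t{r.state}\t{r.ltr_len}\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthSet":
        recs = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                c, s, e, st, f, cl, sf, state, ll = line.rstrip("\n").split("\t")
                recs.append(TruthRecord(c, int(s), int(e), st, f, cl, sf, state, int(ll)))
        return cls(recs)


def _differing_base(base: str) -> str:
    return "C" if base == "A" else "A"


def _n_copies(spec: PlantSpec, family_id: str, rng: np.random.Generator) -> int:
    cpf = spec.copies_per_family
    if isinstance(cpf, Mapping):
        return int(cpf.get(family_id, 0))
    if isinstance(cpf, tuple):
        return int(rng.integers(cpf[0], cpf[1] + 1))
    return int(cpf)


def _realise_copy(bp: ElementBlueprint, spec: PlantSpec, rng: np.random.Generator,
                  library: Sequence[ElementBlueprint]) -> tuple[str, str, str]:
    """(sequence on + orientation of the plant, state, strand)."""
    state = "full"
    seq = bp.element_seq
    u = rng.random()
    if u < spec.solo_ltr_prob:
        state = "solo_ltr"
        seq = bp.ltr_seq
    elif u < spec.solo_ltr_prob + spec.truncation_prob:
        state = "truncated"
        frac = rng.uniform(0.2, 0.8)
        cut = int(round(frac * len(seq)))
        seq = seq[cut:] if rng.random() < 0.5 else seq[: len(seq) - cut]
    elif u < spec.solo_ltr_prob + spec.truncation_prob + spec.nesting_prob and len(library) > 1:
        state = "nested_host"
        others = [b for b in library if b.family_id != bp.family_id]
        guest = others[int(rng.integers(len(others)))]
        mid = len(bp.ltr_seq) + len(bp.internal_seq) // 2
        seq = seq[:mid] + guest.element_seq + seq[mid:]
    if spec.sub_rate > 0 or spec.indel_rate > 0:
        seq = mutate_sequence(seq, spec.sub_rate, spec.indel_rate,
                              spec.mean_indel_len, rng=rng)
    strand = "-" if rng.random() < spec.minus_strand_prob else "+"
    return seq, state, strand


def plant_copies(library: Sequence[ElementBlueprint], spec: PlantSpec
                 ) -> tuple[dict[str, str], TruthSet]:
    """Insert mutated copies of library families into random background contigs.

    Returns ({contig: sequence}, TruthSet). Genome length equals background
    length plus the summed planted-copy lengths. Copies never overlap;
    insertion points keep ``min_spacing`` bp of background between plants.
    Raises PlacementError naming the first copy that cannot be placed.
    """
    rng = np.random.default_rng(spec.seed)
    plants: list[tuple[str, str, str, ElementBlueprint]] = []  # seq, state, strand, bp
    for bp in library:
        for i in range(_n_copies(spec, bp.family_id, rng)):
            seq, state, strand = _realise_copy(bp, spec, rng, library)
            plants.append((seq, state, strand, bp))
    order = rng.permutation(len(plants))

    contig_names = [f"contig{i + 1}" for i in range(spec.n_contigs)]
    points: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}  # (bg_pos, plant_idx)
    for idx in order:
        placed = False
        tries = 0
        while tries < 200 and not placed:
            tries += 1
            contig = contig_names[int(rng.integers(spec.n_contigs))]
            pos = int(rng.integers(0, spec.contig_length))
            if all(abs(pos - p) >= spec.min_spacing for p, _ in points[contig]):
                points[contig].append((pos, int(idx)))
                placed = True
        if not placed:
            bp = plants[int(idx)][3]
            raise PlacementError(
                f"could not place copy of family {bp.family_id}: contigs saturated "
                f"(raise contig_length or lower copies_per_family)")

    genome: dict[str, str] = {}
    truth = TruthSet()
    for contig in contig_names:
        background = list(random_dna(spec.contig_length, rng, spec.gc))
        parts: list[str] = []
        cursor = 0
        offset = 0
        for pos, idx in sorted(points[contig]):
            seq, state, strand, bp = plants[idx]
            oriented = revcomp(seq) if strand == "-" else seq
            if state in ("full", "nested_host") and len(oriented) > bp.ltr_len:
                # guard bases: stop the maximal exact repeat at the planted LTR
                # boundary, so detected spans equal truth spans at zero mutation
                if pos > 0:
                    background[pos - 1] = _differing_base(oriented[-bp.ltr_len - 1])
                if pos < spec.contig_length:
                    background[pos] = _differing_base(oriented[bp.ltr_len])
            parts.append("".join(background[cursor:pos]))
            start = pos + offset
            parts.append(oriented)
            truth.records.append(TruthRecord(
                contig=contig, start=start, end=start + len(oriented), strand=strand,
                family_id=bp.family_id, clade_id=bp.clade_id, superfamily=bp.superfamily,
                state=state, ltr_len=bp.ltr_len))
            offset += len(oriented)
            cursor = pos
        parts.append("".join(background[cursor:]))
        genome[contig] = "".join(parts)
    truth.records.sort(key=lambda r: (r.contig, r.start))
    return genome, truth
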