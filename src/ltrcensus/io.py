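"""FASTA / GFF3 / TSV input-output helpers.

All coordinates are 0-based half-open in memory; GFF3 output converts to
1-based inclusive as the format requires.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgtNnRYSWKMBDHVryswkmbdhv", "TGCAtgcaNnYRSWMKVHDByrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str] | Iterable[tuple[str, str]], path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def fasta_string(seqs: Mapping[str, str]) -> str:
    buf = _io.StringIO()
    for name, s in seqs.items():
        buf.write(f">{name}\n")
        for i in range(0, len(s), 70):
            buf.write(s[i : i + 70] + "\n")
    return buf.getvalue()


def write_gff3(features, path) -> None:
    """Write features as GFF3.

    ``features`` is an iterable of (seqid, source, type, start0, end0, score,
    strand, attributes-dict) with 0-based half-open spans.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start, end, score, strand, attrs in features:
            score_s = "." if score is None else f"{score:.3g}"
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start + 1}\t{end}\t{score_s}\t{strand}\t.\t{attr_s}\n"
            )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
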