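"""Sequence and annotation IO helpers.

FASTA goes through Biopython; GFF3 and TSV are emitted directly.
All genomic coordinates are 0-based half-open internally and converted to
1-based inclusive only at the output boundary.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """i.i.d. uniform A/C/G/T string of length ``n`` (GC content 0.5)."""
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=n)])


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    """Write sequences as 60-column-wrapped FASTA."""
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def fasta_string(seqs: Mapping[str, str]) -> str:
    buf = _io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=60)
    writer.write_file(SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items())
    return buf.getvalue()


def write_gff3(path: str | Path, rows: Iterable[dict]) -> None:
    """Write mobile-element features.

    Each row needs: contig, start, end (0-based half-open), strand and an
    ``attributes`` mapping. Coordinates become 1-based inclusive on output.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            attrs = ";".join(f"{k}={v}" for k, v in r["attributes"].items())
            fh.write(
                "\t".join(
                    [
                        r["contig"],
                        "r2scan",
                        r.get("type", "mobile_genetic_element"),
                        str(r["start"] + 1),
                        str(r["end"]),
                        str(r.get("score", ".")),
                        r.get("strand", "+"),
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def translate(orf_nt: str) -> str:
    """Translate an ORF nucleotide sequence (standard code, no trailing stop)."""
    trimmed = orf_nt[: len(orf_nt) - len(orf_nt) % 3]
    return str(Seq(trimmed).translate()).rstrip("*")
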