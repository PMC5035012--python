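"""Virtual PCR with IUPAC-degenerate primers.

Reproduces the amplification strategy used to recover R2 3′ halves from
genomic DNA: a degenerate forward primer in the conserved RT domain paired
with a reverse primer in the 28S rRNA gene downstream of the insertion site.
All eight published primers are built in by name.

Matching is exact per IUPAC code by default (a template base must be in the
primer code's allowed set; ambiguity codes in the template match only by
code identity). An optional mismatch budget models primer-site divergence,
which in practice explains PCR failures on diverged families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .io import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: The published primer set: four RT-domain forward primers and four 28S
#: reverse primers (named by position relative to the insertion site).
BUILTIN_PRIMERS: dict[str, str] = {
    "R2IF1": "AAGCARGGNGAYCCNCTNTC",
    "R2IIF1": "GTNAARCARGGNGAYCCNCT",
    "R2IF2": "GCYYTRGCGTTYGCNGAYGA",
    "R2IIF2": "CTNGCNTTYGCNGAYGAYYT",
    "28S_R-198": "GCCTCCCACTTATYCTACACC",
    "28S_R-147": "GTCAAGCTCAACAGGGTCTTCT",
    "28S_R-B": "ATCCATTCATGCGCGTCACT",
    "28S_R-A": "TAGATGACGAGGCATTTGGC",
}


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty primer sequence")
        for i, c in enumerate(self.sequence.upper()):
            if c not in IUPAC:
                raise ValueError(f"invalid IUPAC code {c!r} at position {i + 1} "
                                 f"of primer {self.name}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class AmpliconCall:
    """A predicted product; start/end are 0-based half-open outermost primer
    bases on the reported strand of the contig."""

    contig: str
    start: int
    end: int
    fwd_primer: str
    rev_primer: str
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


def get_primer(name_or_seq: str) -> Primer:
    """Resolve a built-in primer name, else treat the string as a sequence."""
    if name_or_seq in BUILTIN_PRIMERS:
        return Primer(name_or_seq, BUILTIN_PRIMERS[name_or_seq])
    return Primer(name_or_seq, name_or_seq)


def degeneracy(primer: Primer | str) -> int:
    """Number of concrete sequences the degenerate primer represents."""
    p = primer if isinstance(primer, Primer) else get_primer(primer)
    n = 1
    for c in p.sequence:
        n *= len(IUPAC[c])
    return n


def iupac_match(primer: Primer | str, template: str, pos: int,
                max_mismatch: int = 0) -> bool:
    """Does the primer anneal to ``template`` starting at ``pos``?

    Template ambiguity codes are treated as non-matching unless identical to
    the primer code.
    """
    p = primer if isinstance(primer, Primer) else get_primer(primer)
    seq = p.sequence
    if pos < 0 or pos + len(seq) > len(template):
        raise ValueError(f"position {pos} out of range for primer {p.name}")
    mism = 0
    for c_p, c_t in zip(seq, template[pos:pos + len(seq)]):
        if c_t in "ACGT":
            ok = c_t in IUPAC[c_p]
        else:
            ok = c_t == c_p
        if not ok:
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def _sites(primer: Primer, template: str, max_mismatch: int) -> list[int]:
    m = len(primer.sequence)
    return [i for i in range(len(template) - m + 1)
            if iupac_match(primer, template, i, max_mismatch)]


def virtual_pcr(
    template: Mapping[str, str] | str,
    fwd: Primer | str,
    rev: Primer | str,
    max_len: int = 3000,
    max_mismatch: int = 0,
) -> list[AmpliconCall]:
    """All products ≤ max_len from (fwd on one strand, rev on the other).

    Both orientations are scanned: '+' amplicons have the forward primer on
    the plus strand; '−' amplicons satisfy the same geometry on the reverse
    complement (coordinates still reported on the plus strand). Nested
    products are all reported; deduplication is the caller's concern.
    """
    fwd = fwd if isinstance(fwd, Primer) else get_primer(fwd)
    rev = rev if isinstance(rev, Primer) else get_primer(rev)
    if max_len <= len(fwd.sequence) + len(rev.sequence):
        raise ValueError("max_len must exceed the combined primer length")
    contigs = {"template": template} if isinstance(template, str) else template
    out: list[AmpliconCall] = []
    for contig, seq in contigs.items():
        seq = seq.upper()
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            f_sites = _sites(fwd, s, max_mismatch)
            r_probe = Primer(rev.name, revcomp(rev.sequence))
            r_sites = _sites(r_probe, s, max_mismatch)
            for f in f_sites:
                for r in r_sites:
                    end = r + len(rev.sequence)
                    if end - f > max_len or end <= f:
                        continue
                    if strand == "+":
                        start_plus, end_plus = f, end
                    else:
                        start_plus, end_plus = len(s) - end, len(s) - f
                    out.append(AmpliconCall(contig=contig, start=start_plus,
                                            end=end_plus, fwd_primer=fwd.name,
                                            rev_primer=rev.name, strand=strand))
    out.sort(key=lambda a: (a.contig, a.start, a.end, a.strand))
    return out


def amplicon_table(calls: list[AmpliconCall]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [dict(contig=a.contig, start=a.start + 1, end=a.end, length=a.length,
              strand=a.strand, fwd_primer=a.fwd_primer, rev_primer=a.rev_primer)
         for a in calls],
        columns=["contig", "start", "end", "length", "strand",
                 "fwd_primer", "rev_primer"],
    )
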