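"""Synthetic rDNA-array genomes with R2-like insertions of known geometry.

The simulator emulates the situation the analysis modules are built for: a
tandem array of 28S rRNA gene units, some units carrying an element copy
spliced in at the canonical insertion site or at a configurable 5′/3′ offset
(the "apparent movement" geometries: 110 and 130 bp of 28S replaced upstream
of the site), plus non-specifically inserted copies dropped into intergenic
spacer, 5′-truncated copies, and per-copy mutational decay. Every insertion
is recorded in a ground-truth table so recovery can be scored exactly.

The synthetic 28S core is built from the two downstream 28S PCR primers
(28S_R-A, 28S_R-B): the core is revcomp(28S_R-A) ++ revcomp(28S_R-B) with
the canonical insertion site at the junction of the two 20-mers. This is a
documented synthetic convention, not a claim about the biological 28S
sequence; it guarantees that a reverse primer binding site sits immediately
downstream of a canonical insertion and another immediately upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import substream
from .io import DNA, fasta_string, random_dna, revcomp, translate, write_fasta, write_gff3

# Printed 28S reverse primers; the synthetic 28S core is their reverse complement.
PRIMER_28S_R_A = "TAGATGACGAGGCATTTGGC"
PRIMER_28S_R_B = "ATCCATTCATGCGCGTCACT"

# Concrete (non-degenerate) instantiations of the two RT-domain forward
# primers, padded to a codon multiple; both translate without stops and
# without Cys/His residues so they can never seed a spurious zinc finger.
R2IF2_SITE = "GCCTTAGCGTTCGCAGACGA" + "C"      # matches GCYYTRGCGTTYGCNGAYGA
R2IIF2_SITE = "CTGGCATTCGCAGACGACTT" + "G"     # matches CTNGCNTTYGCNGAYGAYYT

RIBOZYME_MOTIF = "CCTCCTCGTGG"  # DNA form of the conserved HDV-like ribozyme core

CLADE_FINGERS = {
    "R2A": ("CCHH", "CCHH", "CCHC"),
    "R2B": ("CCHH", "CCHC"),
    "R2C": ("CCHH", "CCHH"),
    "R2D": ("CCHH",),
}

# Sense codons that encode neither Cys nor His nor a stop: filler drawn from
# these can never complete a zinc-finger pattern on its own.
_SAFE_CODONS = [
    c1 + c2 + c3
    for c1 in DNA for c2 in DNA for c3 in DNA
    if c1 + c2 + c3 not in {"TAA", "TAG", "TGA", "TGT", "TGC", "CAT", "CAC"}
]
_AA_CODON = {"C": "TGC", "H": "CAC", "G": "GGC", "K": "AAG", "S": "TCC",
             "R": "CGC", "E": "GAG", "L": "CTG", "F": "TTC", "A": "GCC"}
_SPACER_AA = "GKSRELFA"  # finger spacer residues (no C/H)


@dataclass
class TargetReference:
    """A 28S (or 18S) gene with one annotated canonical insertion site."""

    name: str
    sequence: str
    canonical_site: int
    gene_label: str = "28S"

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set(DNA):
            raise ValueError("target sequence must be non-empty unambiguous A/C/G/T")
        if not 0 <= self.canonical_site <= len(self.sequence):
            raise ValueError("canonical_site outside sequence")


@dataclass
class InsertionSpec:
    """One planned insertion.

    offset5/offset3 are the number of target bases upstream/downstream of the
    canonical site removed (replaced) by the insertion; 0/0 is canonical.
    """

    family_id: str
    offset5: int = 0
    offset3: int = 0
    truncate5: int = 0
    nonspecific: bool = False
    divergence: float = 0.0
    indels: bool = False
    unit_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.offset5 < 0 or self.offset3 < 0 or self.truncate5 < 0:
            raise ValueError("offsets and truncation must be non-negative")
        if self.nonspecific and (self.offset5 or self.offset3):
            raise ValueError("nonspecific insertions take no junction offsets")
        if not 0.0 <= self.divergence < 0.5:
            raise ValueError("divergence must be in [0, 0.5)")


@dataclass
class ElementFamily:
    """A simulated element family: consensus, ORF, protein, and provenance."""

    family_id: str
    clade: str
    consensus: str
    orf_start: int
    orf_end: int
    ribozyme_pos: Optional[int] = None     # 0-based start of motif in consensus
    utr3_segment: Optional[tuple[int, int]] = None  # consensus coords of 28S-like block
    utr3_identity: Optional[float] = None  # realised identity of that block

    @property
    def protein(self) -> str:
        return translate(self.consensus[self.orf_start:self.orf_end])


@dataclass
class GenomeBundle:
    """Synthetic genome plus the simulator's ground truth."""

    genome: dict[str, str]
    truth: pd.DataFrame
    target: TargetReference
    families: dict[str, ElementFamily] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", self.genome)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        write_fasta(outdir / "target.fa", {self.target.name: self.target.sequence})
        if self.families:
            write_fasta(outdir / "families.fa",
                        {f.family_id: f.consensus for f in self.families.values()})
        write_gff3(
            outdir / "truth.gff3",
            (
                {
                    "contig": r.contig,
                    "start": int(r.start),
                    "end": int(r.end),
                    "strand": r.strand,
                    "attributes": {
                        "ID": r.copy_id,
                        "family_id": r.family_id,
                        "offset5": int(r.offset5),
                        "offset3": int(r.offset3),
                        "nonspecific": str(bool(r.nonspecific)).lower(),
                    },
                }
                for r in self.truth.itertuples()
            ),
        )

    def fasta(self) -> str:
        return fasta_string(self.genome)


def _count_occurrences(genome: str, probe: str) -> int:
    n = 0
    for hay in (genome, revcomp(genome)):
        start = 0
        while True:
            i = hay.find(probe, start)
            if i < 0:
                break
            n += 1
            start = i + 1
    return n


def build_target_reference(flank_len: int = 200, seed: int = 0,
                           gene_label: str = "28S") -> TargetReference:
    """Synthetic 28S gene: revcomp(28S_R-A) ++ revcomp(28S_R-B) core, random flanks.

    The canonical insertion site is the boundary between the two primer-derived
    20-mers, at coordinate ``flank_len + 20``. Both primer binding sites are
    guaranteed unique in the returned sequence (either strand).
    """
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    core = revcomp(PRIMER_28S_R_A) + revcomp(PRIMER_28S_R_B)
    rng = substream(seed, "target")
    while True:
        seq = random_dna(rng, flank_len) + core + random_dna(rng, flank_len)
        if (_count_occurrences(seq, revcomp(PRIMER_28S_R_A)) == 1
                and _count_occurrences(seq, revcomp(PRIMER_28S_R_B)) == 1):
            break
    return TargetReference(name=f"{gene_label}_synthetic", sequence=seq,
                           canonical_site=flank_len + 20, gene_label=gene_label)


def mutate(seq: str, sub_rate: float, rng: np.random.Generator,
           indels: bool = False) -> str:
    """Per-base substitution decay, optional indels at 1/10 the rate.

    Indel lengths are geometric with mean 2; insertions are uniform random
    bases. Substitutions always change the base.
    """
    if sub_rate == 0.0 and not indels:
        return seq
    bases = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = {b: [x for x in b"ACGT" if x != b] for b in b"ACGT"}
    hit = rng.random(len(bases)) < sub_rate
    for i in np.flatnonzero(hit):
        bases[i] = rng.choice(lut[bases[i]])
    out = bases.tobytes().decode()
    if indels and sub_rate > 0:
        indel_rate = sub_rate / 10.0
        pieces: list[str] = []
        last = 0
        for i in np.flatnonzero(rng.random(len(out)) < indel_rate):
            length = int(rng.geometric(0.5))
            pieces.append(out[last:i])
            if rng.random() < 0.5:
                pieces.append(random_dna(rng, length))  # insertion
                pieces.append(out[i])
                last = i + 1
            else:
                last = min(len(out), i + length)        # deletion
        pieces.append(out[last:])
        out = "".join(pieces)
    return out


def _finger_codons(kind: str, rng: np.random.Generator) -> str:
    """Codons encoding C-x3-C-x12-H-x4-(H|C) with inert spacer residues."""
    aa = ("C" + _spacer(3, rng) + "C" + _spacer(12, rng) + "H"
          + _spacer(4, rng) + kind[3])
    return "".join(_AA_CODON[a] for a in aa)


def _spacer(n: int, rng: np.random.Generator) -> str:
    return "".join(_SPACER_AA[i] for i in rng.integers(0, len(_SPACER_AA), n))


def _filler_codons(n: int, rng: np.random.Generator) -> str:
    return "".join(_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n))


def simulate_element_family(
    clade: str,
    total_len: int = 3000,
    utr3_target_segment: Optional[tuple[int, float]] = None,
    ribozyme: bool = False,
    seed: int = 0,
    family_id: Optional[str] = None,
    target: Optional[TargetReference] = None,
    ribozyme_pos: int = 36,
    utr5_len: int = 300,
    utr3_len: int = 700,
) -> ElementFamily:
    """Build a clade-typed element consensus.

    The single long ORF carries, 5′→3′, the clade's zinc-finger complement and
    an RT block with exact binding sites for primers R2IF2 and R2IIF2. If
    ``ribozyme`` is set the conserved motif is embedded in the 5′ UTR at
    ``ribozyme_pos`` (0-based; default reproduces a motif at nucleotides 37–47,
    1-based). ``utr3_target_segment=(length, identity)`` embeds a decayed copy
    of the target's downstream-of-site sequence in the 3′ UTR, emulating a
    28S-derived 3′ UTR; it requires ``target``.
    """
    if clade not in CLADE_FINGERS:
        raise ValueError(f"unknown clade {clade!r}")
    if total_len < 2000:
        raise ValueError("total_len must be >= 2000")
    if utr3_target_segment is not None:
        seg_len, seg_ident = utr3_target_segment
        if not 0.5 < seg_ident <= 1.0:
            raise ValueError("utr3 segment identity must be in (0.5, 1.0]")
        if target is None:
            raise ValueError("utr3_target_segment requires a target reference")
    rng = substream(seed, f"family:{clade}:{family_id or ''}")

    orf_len_nt = total_len - utr5_len - utr3_len
    n_codons = orf_len_nt // 3 - 1  # minus start codon
    zf_codons = "".join(
        _finger_codons(kind, rng) + _filler_codons(6, rng)
        for kind in CLADE_FINGERS[clade]
    )
    # RT block sits in the second half of the ORF: forward primer sites in the
    # order a nested PCR would use them, 10 inert codons apart.
    rt_block = R2IF2_SITE + _filler_codons(10, rng) + R2IIF2_SITE
    used = len(zf_codons) // 3 + len(rt_block) // 3
    mid_fill = max(0, (n_codons - used) * 55 // 100)
    tail_fill = n_codons - used - mid_fill
    if tail_fill < 0:
        raise ValueError("total_len too short for ORF layout")
    orf = ("ATG" + zf_codons + _filler_codons(mid_fill, rng) + rt_block
           + _filler_codons(tail_fill, rng))

    utr5 = random_dna(rng, utr5_len)
    if ribozyme:
        if ribozyme_pos + len(RIBOZYME_MOTIF) > utr5_len:
            raise ValueError("ribozyme_pos outside the 5' UTR")
        utr5 = (utr5[:ribozyme_pos] + RIBOZYME_MOTIF
                + utr5[ribozyme_pos + len(RIBOZYME_MOTIF):])

    utr3 = random_dna(rng, total_len - utr5_len - len(orf) - 3)
    utr3_interval = None
    realised_identity = None
    if utr3_target_segment is not None:
        seg_len, seg_ident = utr3_target_segment
        src = target.sequence[target.canonical_site:
                              target.canonical_site + seg_len]
        # exact substitution count so the realised identity hits the request
        n_sub = round((1.0 - seg_ident) * len(src))
        sites = rng.choice(len(src), size=n_sub, replace=False)
        seg_list = list(src)
        for i in sites:
            seg_list[i] = DNA[(DNA.index(seg_list[i]) + 1 + rng.integers(0, 3)) % 4]
        seg = "".join(seg_list)
        # place the segment so it ends 20 bp before the element 3' terminus
        pos = len(utr3) - 20 - len(seg)
        if pos < 0:
            raise ValueError("3' UTR too short for the requested segment")
        utr3 = utr3[:pos] + seg + utr3[pos + len(seg):]
        n_match = sum(a == b for a, b in zip(seg, src))
        realised_identity = n_match / len(src)
        off = utr5_len + len(orf) + 3
        utr3_interval = (off + pos, off + pos + len(seg))

    consensus = utr5 + orf + "TAA" + utr3
    fam = ElementFamily(
        family_id=family_id or f"{clade}_sim",
        clade=clade,
        consensus=consensus,
        orf_start=utr5_len,
        orf_end=utr5_len + len(orf),
        ribozyme_pos=ribozyme_pos if ribozyme else None,
        utr3_segment=utr3_interval,
        utr3_identity=realised_identity,
    )
    assert len(fam.consensus) == total_len
    return fam


def insert_copies(
    target: TargetReference,
    families: list[ElementFamily],
    specs: list[InsertionSpec],
    n_units: int = 6,
    spacer_len: int = 400,
    seed: int = 0,
    contig_name: str = "rdna_array",
) -> GenomeBundle:
    """Assemble a tandem rDNA array carrying the requested insertions.

    The contig is spacer + (unit + spacer) × n_units. Each site-specific spec
    consumes one unit (in order, or at its ``unit_index``), removing offset5
    bases upstream and offset3 bases downstream of the canonical site and
    splicing in the decayed, possibly 5′-truncated element. Non-specific specs
    land at uniform random positions inside spacer sequence.
    """
    fam_by_id = {f.family_id: f for f in families}
    site_specs = [s for s in specs if not s.nonspecific]
    ns_specs = [s for s in specs if s.nonspecific]
    if len(site_specs) > n_units:
        raise ValueError("more site-specific specs than rDNA units")
    cs = target.canonical_site
    for s in site_specs:
        if s.offset5 > cs or cs + s.offset3 > len(target.sequence):
            raise ValueError(f"offsets of {s.family_id} exceed target bounds")
    for s in specs:
        if s.family_id not in fam_by_id:
            raise ValueError(f"unknown family {s.family_id}")

    rng = substream(seed, "insert")
    # assign units
    unit_spec: dict[int, InsertionSpec] = {}
    free = iter(u for u in range(n_units)
                if u not in {s.unit_index for s in site_specs if s.unit_index is not None})
    for s in site_specs:
        u = s.unit_index if s.unit_index is not None else next(free)
        if u in unit_spec or not 0 <= u < n_units:
            raise ValueError(f"bad unit assignment for {s.family_id}")
        unit_spec[u] = s

    spacers = [random_dna(rng, spacer_len) for _ in range(n_units + 1)]
    # Nonspecific placements: uniform over spacer interiors, keeping an
    # 80 bp margin from unit boundaries so a "non-specific" copy is never
    # incidentally adjacent to rDNA sequence (its truth label must be
    # recoverable from its flanks).
    margin = min(80, spacer_len // 3)
    if ns_specs and spacer_len - 2 * margin <= 0:
        raise ValueError("spacer_len too short for nonspecific insertions")
    ns_place = sorted(
        ((int(rng.integers(0, n_units + 1)),
          int(rng.integers(margin, spacer_len - margin + 1)), s)
         for s in ns_specs),
        key=lambda x: (x[0], x[1]),
    )

    pieces: list[str] = []
    rows: list[dict] = []
    pos = 0
    copy_no = 0

    def emit(seq: str) -> None:
        nonlocal pos
        pieces.append(seq)
        pos += len(seq)

    def emit_copy(spec: InsertionSpec) -> None:
        nonlocal copy_no
        fam = fam_by_id[spec.family_id]
        elem = fam.consensus[spec.truncate5:]
        elem = mutate(elem, spec.divergence, rng, indels=spec.indels)
        rows.append(dict(
            copy_id=f"copy{copy_no:03d}", family_id=spec.family_id,
            contig=contig_name, start=pos, end=pos + len(elem), strand="+",
            offset5=spec.offset5, offset3=spec.offset3,
            truncate5=spec.truncate5, nonspecific=spec.nonspecific,
            divergence=spec.divergence,
        ))
        copy_no += 1
        emit(elem)

    for u in range(n_units + 1):
        spacer = spacers[u]
        cut = 0
        for sp_idx, off, s in ns_place:
            if sp_idx == u:
                emit(spacer[cut:off])
                emit_copy(s)
                cut = off
        emit(spacer[cut:])
        if u == n_units:
            break
        spec = unit_spec.get(u)
        if spec is None:
            emit(target.sequence)
        else:
            emit(target.sequence[:cs - spec.offset5])
            emit_copy(spec)
            emit(target.sequence[cs + spec.offset3:])

    truth = pd.DataFrame(
        rows,
        columns=["copy_id", "family_id", "contig", "start", "end", "strand",
                 "offset5", "offset3", "truncate5", "nonspecific", "divergence"],
    )
    truth = truth.sort_values(["contig", "start"], kind="stable").reset_index(drop=True)
    return GenomeBundle(genome={contig_name: "".join(pieces)}, truth=truth,
                        target=target, families=fam_by_id)


def simulate_clade_protein_set(
    n_per_clade: int = 3,
    length: int = 300,
    within_divergence: float = 0.1,
    seed: int = 0,
) -> dict[str, str]:
    """Protein families for clade-recovery tests: 4 independent random clade
    ancestors, each mutated into ``n_per_clade`` descendants.

    Between-clade distances are near saturation while within-clade distances
    stay around ``within_divergence``, so clade monophyly is the expected
    outcome of any sound distance method.
    """
    rng = substream(seed, "clade-proteins")
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out: dict[str, str] = {}
    for clade in CLADE_FINGERS:
        anc = aa[rng.integers(0, 20, length)]
        for i in range(n_per_clade):
            seq = anc.copy()
            hit = np.flatnonzero(rng.random(length) < within_divergence)
            for j in hit:
                choices = [a for a in aa if a != seq[j]]
                seq[j] = choices[rng.integers(0, len(choices))]
            out[f"{clade}_fam{i + 1}"] = "".join(seq)
    return out
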