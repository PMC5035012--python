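"""End-to-end orchestration.

simulate (or ingest) → find copies → call junctions → classify families →
detect 28S-like 3′ UTRs → type clades → rebuild consensuses → distance tree,
with every artifact written under one output directory and a per-family
summary row returned. A run is a pure function of (config, seed): the
resolved config is written verbatim, every stage draws from its own named
RNG substream, and the report is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from ._rng import substream
from . import consensus as cons_mod
from . import junctions as junc_mod
from . import motifscan
from . import phylo
from .io import read_fasta, write_fasta, write_gff3
from .syngenome import (ElementFamily, GenomeBundle, InsertionSpec,
                        TargetReference, build_target_reference, insert_copies,
                        simulate_element_family)


@dataclass
class SimSpec:
    """Simulation block of a run config (all study-condition knobs)."""

    n_units: int = 8
    spacer_len: int = 400
    flank_len: int = 200
    element_len: int = 3000
    families: list[dict] = field(default_factory=list)
    insertions: list[dict] = field(default_factory=list)


@dataclass
class RunConfig:
    outdir: str = "r2scan_out"
    seed: int = 0
    simulate: Optional[SimSpec] = None
    genome_fasta: Optional[str] = None
    families_fasta: Optional[str] = None
    target_fasta: Optional[str] = None
    canonical_site: Optional[int] = None
    # module parameters, every one with a documented default
    k: int = 12
    min_len: int = 500  # above any 28S-like UTR segment, below real (even truncated) copies
    min_identity: float = 0.7
    window: int = 60
    min_flank_identity: float = 0.8
    tol5: int = 2
    tol3: int = 0
    specific_fraction: float = 0.9
    utr_min_hit_len: int = 30
    gap_rule_fraction: float = 0.5
    bootstrap_reps: int = 100

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimSpec(**sim)
        return cfg


@dataclass
class RunReport:
    rows: pd.DataFrame
    seed: int
    version: str
    config_hash: str
    tree_newick: Optional[str] = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def default_demo_config(outdir: str = "r2scan_out", seed: int = 0) -> RunConfig:
    """Demo study: four families, one per clade.

    famA (R2A): canonical, 3 copies. famB (R2B): 5′ junction shifted 110 bp
    with a 28S-derived 3′ UTR segment, 2 copies. famC (R2C): canonical,
    2 copies. famD (R2D): non-specific, 3 copies.
    """
    sim = SimSpec(
        families=[
            dict(family_id="famA", clade="R2A", ribozyme=True),
            dict(family_id="famB", clade="R2B", utr3_target_segment=[150, 0.85]),
            dict(family_id="famC", clade="R2C"),
            dict(family_id="famD", clade="R2D"),
        ],
        insertions=(
            [dict(family_id="famA", divergence=0.02)] * 3
            + [dict(family_id="famB", offset5=110, divergence=0.02)] * 2
            + [dict(family_id="famC", divergence=0.02)] * 2
            + [dict(family_id="famD", nonspecific=True, divergence=0.02)] * 3
        ),
    )
    return RunConfig(outdir=outdir, seed=seed, simulate=sim)


def _config_hash(cfg: RunConfig) -> str:
    d = cfg.to_dict()
    d.pop("outdir", None)  # hash the scientific config, not the destination
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _simulate(cfg: RunConfig) -> GenomeBundle:
    sim = cfg.simulate
    target = build_target_reference(flank_len=sim.flank_len, seed=cfg.seed)
    families = []
    for i, f in enumerate(sim.families):
        f = dict(f)
        seg = f.get("utr3_target_segment")
        families.append(simulate_element_family(
            clade=f["clade"],
            total_len=f.get("total_len", sim.element_len),
            utr3_target_segment=tuple(seg) if seg else None,
            ribozyme=f.get("ribozyme", False),
            seed=cfg.seed + i,
            family_id=f["family_id"],
            target=target,
        ))
    specs = [InsertionSpec(**s) for s in sim.insertions]
    return insert_copies(target, families, specs, n_units=sim.n_units,
                         spacer_len=sim.spacer_len, seed=cfg.seed)


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline; artifacts land in ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest: list[str] = []

    def done(stage: str) -> None:
        manifest.append(stage)
        (out / "MANIFEST").write_text(
            "\n".join(manifest) + "\n")

    try:
        stage = "input"
        if config.simulate is not None:
            bundle = _simulate(config)
            bundle.write(out / "sim")
            genome = bundle.genome
            fam_seqs = {f.family_id: f.consensus for f in bundle.families.values()}
            families = bundle.families
            target = bundle.target
            truth: Optional[pd.DataFrame] = bundle.truth
        else:
            genome = read_fasta(config.genome_fasta)
            fam_seqs = read_fasta(config.families_fasta)
            tgt = read_fasta(config.target_fasta)
            name, seq = next(iter(tgt.items()))
            target = TargetReference(name=name, sequence=seq,
                                     canonical_site=int(config.canonical_site))
            families = {}
            truth = None
        done(stage)

        stage = "find_copies"
        copies: dict[str, list[junc_mod.ElementCopy]] = {}
        for fid, fseq in fam_seqs.items():
            copies[fid] = junc_mod.find_copies(
                genome, fseq, family_id=fid, k=config.k,
                min_len=config.min_len, min_identity=config.min_identity)
        all_copies = [c for cs in copies.values() for c in cs]
        write_gff3(out / "copies.gff3", (
            dict(contig=c.contig, start=c.start, end=c.end, strand=c.strand,
                 attributes=dict(ID=c.copy_id, family_id=c.family_id,
                                 identity=c.identity_to_consensus))
            for c in sorted(all_copies, key=lambda c: (c.contig, c.start))))
        done(stage)

        stage = "call_junctions"
        calls: dict[str, list[junc_mod.JunctionCall]] = {}
        call_rows = []
        for fid, cs_ in copies.items():
            calls[fid] = [junc_mod.call_junctions(
                c, genome, target, window=config.window,
                min_flank_identity=config.min_flank_identity,
                tol5=config.tol5, tol3=config.tol3) for c in cs_]
            for c, jc in zip(cs_, calls[fid]):
                call_rows.append(dict(
                    copy_id=c.copy_id, family_id=fid, contig=c.contig,
                    start=c.start + 1, end=c.end, strand=c.strand,
                    identity=c.identity_to_consensus,
                    offset5="" if jc.offset5 is None else jc.offset5,
                    offset3="" if jc.offset3 is None else jc.offset3,
                    specificity=jc.specificity, flags=",".join(jc.flags)))
        pd.DataFrame(call_rows).to_csv(out / "junctions.tsv", sep="\t", index=False)
        done(stage)

        stage = "classify_families"
        verdicts = {fid: junc_mod.classify_family(
            calls[fid], specific_fraction=config.specific_fraction, family_id=fid)
            for fid in calls if calls[fid]}
        done(stage)

        stage = "detect_utr"
        utr_calls = {}
        for fid, fseq in fam_seqs.items():
            flank_idents = [jc.flank3_hit.identity for jc in calls.get(fid, [])
                            if jc.flank3_hit is not None
                            and jc.flank3_hit.identity >= config.min_flank_identity]
            flank_ident = max(flank_idents) if flank_idents else 1.0
            utr_calls[fid] = junc_mod.detect_target_like_utr(
                families.get(fid, fseq), target, flank_identity=flank_ident,
                min_hit_len=config.utr_min_hit_len, family_id=fid)
        done(stage)

        stage = "motifscan"
        clades = {}
        for fid, fseq in fam_seqs.items():
            if fid in families:
                protein = families[fid].protein
            else:
                protein = _longest_orf_protein(fseq)
            clades[fid] = (motifscan.classify_protein(protein)
                           if protein else motifscan.classify_clade([]))
        done(stage)

        stage = "consensus"
        rebuilt = {}
        for fid, fseq in fam_seqs.items():
            seqs = {c.copy_id: _copy_seq(genome, c) for c in copies[fid]
                    if c.end - c.start >= 0.9 * len(fseq)}
            if len(seqs) >= 2:
                aln = cons_mod.align_to_reference(fseq, seqs, family_id=fid)
                rebuilt[fid] = cons_mod.majority_consensus(
                    aln, gap_rule_fraction=config.gap_rule_fraction)
        if rebuilt:
            write_fasta(out / "consensus.fa", rebuilt)
        done(stage)

        stage = "tree"
        tree_newick = None
        if len(fam_seqs) >= 3:
            prots = {fid: (families[fid].protein if fid in families
                           else _longest_orf_protein(fs)) for fid, fs in fam_seqs.items()}
            prots = {k: v for k, v in prots.items() if v}
            if len(prots) >= 3:
                ref = max(prots.values(), key=len)
                rows = cons_mod.star_align(ref, prots)
                tree = phylo.bootstrap_support(rows, n_reps=config.bootstrap_reps,
                                               seed=config.seed)
                tree_newick = tree.newick()
                (out / "tree.nwk").write_text(tree_newick + "\n")
        done(stage)

        stage = "report"
        rows = []
        for fid in sorted(fam_seqs):
            v = verdicts.get(fid)
            rows.append(dict(
                family_id=fid,
                clade=clades[fid].clade,
                n_copies=v.n_copies if v else 0,
                specificity=v.verdict if v else "no_copies",
                modal_offset5="" if v is None or v.modal_offset5 is None
                else v.modal_offset5,
                utr_28S_like=bool(utr_calls[fid].is_utr_internal),
            ))
        report_df = pd.DataFrame(rows, columns=["family_id", "clade", "n_copies",
                                                "specificity", "modal_offset5",
                                                "utr_28S_like"])
        header = (f"# r2scan {__version__} seed={config.seed} "
                  f"config_hash={cfg_hash}\n")
        (out / "report.tsv").write_text(header + report_df.to_csv(sep="\t", index=False))
        if truth is not None:
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        done(stage)
    except Exception as exc:  # noqa: BLE001 - stage-named abort contract
        (out / "MANIFEST").write_text("\n".join(manifest)
                                      + f"\nINCOMPLETE at {stage}\n")
        raise StageError(stage, exc) from exc

    return RunReport(rows=report_df, seed=config.seed, version=__version__,
                     config_hash=cfg_hash, tree_newick=tree_newick)


def _copy_seq(genome: dict[str, str] | str, c: junc_mod.ElementCopy) -> str:
    from .io import revcomp

    seq = genome if isinstance(genome, str) else genome[c.contig]
    s = seq[c.start:c.end]
    return s if c.strand == "+" else revcomp(s)


def _longest_orf_protein(nt: str, min_aa: int = 100) -> str:
    """Longest stop-free ORF (any frame, forward strand), translated."""
    from .io import translate

    best = ""
    for frame in range(3):
        prot = translate(nt[frame:])
        for piece in prot.split("*"):
            i = piece.find("M")
            if i >= 0 and len(piece) - i > len(best):
                best = piece[i:]
    return best if len(best) >= min_aa else ""
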