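"""Synthetic allopolyploid genome sets with known divergence structure.

The simulator emulates the comparative-genomics setting of a recent
allohexaploid grass: a focal genome whose subgenomes derive from one
polyploidization/hybridization event, plus outgroup genomes split off at
deeper speciation events.  Every gene pair's true divergence is recorded, so
the downstream 4dTv / synteny / dating stages can be validated against ground
truth without any external data.

Divergence is parameterized in transversion-rate time: ``tau`` is the *total*
pairwise divergence beta*t summed over both lineages, where beta is the rate
of each of the two transversion types in a Kimura two-parameter model.  Under
that model the expected fraction of transversion differences between two
sequences separated by ``tau`` is

    Q(tau) = 1/2 * (1 - exp(-4*tau))

which is exactly what the 4dTv statistic estimates at four-fold degenerate
sites.  ``tau_for_target_4dtv`` inverts Q so simulations can be parameterized
directly by observed peak positions (e.g. 0.042).
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DivergenceEvent",
    "SimulationConfig",
    "SimulationTruth",
    "GeneRecord",
    "GenomeSet",
    "simulate_ancestral_genes",
    "evolve_k2p",
    "tau_for_target_4dtv",
    "expected_4dtv",
    "build_genome_set",
    "write_genome_set",
    "fig1b_scenario",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
# transition partner and the two transversion partners of each base
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _derive_seed(*parts: object) -> int:
    """Stable per-stream seed from a root seed plus string tags (order matters)."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class DivergenceEvent:
    """A split in the genome history.

    kind
        ``"wgd"`` duplicates every retained gene lineage of the focal genome
        into ``copies`` subgenome copies; ``"speciation"`` splits off an
        outgroup genome.
    tau
        Total pairwise divergence (beta*t units) between lineages separated
        at this event.  Deeper events have larger tau.
    copies
        Number of copies emitted by a WGD (>= 2); ignored for speciations.
        Three models a hexaploidy whose subgenomes diverged at one level.
    """

    kind: str
    tau: float
    copies: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("wgd", "speciation"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.tau > 0:
            raise ValueError("event tau must be strictly positive")
        if self.kind == "wgd" and self.copies < 2:
            raise ValueError("a WGD must emit at least 2 copies")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 400
    codons_per_gene: int = 120
    kappa: float = 2.0
    events: tuple[DivergenceEvent, ...] = ()
    loss_prob: float = 0.1
    seed: int = 0
    genes_per_chromosome: int = 20
    decoys: bool = False
    decoy_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.codons_per_gene < 10:
            raise ValueError("codons_per_gene must be >= 10")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if not 0 <= self.loss_prob < 1:
            raise ValueError("loss_prob must be in [0, 1)")
        if self.genes_per_chromosome < 1:
            raise ValueError("genes_per_chromosome must be >= 1")
        object.__setattr__(self, "events", tuple(
            e if isinstance(e, DivergenceEvent) else DivergenceEvent(**e)
            for e in self.events
        ))
        taus = [e.tau for e in self.events]
        if any(t2 >= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("event taus must be strictly decreasing (deepest first)")

    @staticmethod
    def from_dict(d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["events"] = tuple(
            DivergenceEvent(**e) if isinstance(e, Mapping) else e
            for e in d.get("events", ())
        )
        return SimulationConfig(**d)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    genome: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    seq: str


@dataclass
class SimulationTruth:
    """Ground-truth gene pairs: (id_a, id_b, relation, true_tau, expected_4dtv)."""

    pairs: pd.DataFrame

    def to_tsv(self, path: os.PathLike | str) -> None:
        _atomic_write_text(path, self.pairs.to_csv(sep="\t", index=False))


@dataclass
class GenomeSet:
    config: SimulationConfig
    genes: dict[str, list[GeneRecord]]  # genome id -> gene records in coordinate order
    hits: pd.DataFrame
    truth: SimulationTruth


def tau_for_target_4dtv(x: float) -> float:
    """Invert Q(tau) = (1 - exp(-4 tau))/2: the tau whose expected 4dTv is ``x``."""
    if not 0 <= x < 0.5:
        raise ValueError("target 4dTv must lie in [0, 0.5); 0.5 is the saturation limit")
    return -math.log(1.0 - 2.0 * x) / 4.0


def expected_4dtv(tau: float) -> float:
    """Expected transversion-difference fraction Q(tau) after total divergence tau."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return 0.5 * (1.0 - math.exp(-4.0 * tau))


def _k2p_outcome_probs(tau: float, kappa: float) -> tuple[float, float, float]:
    """(P[same], P[transition], P[each of the two transversions]) after time tau.

    Two-parameter model with transition rate kappa*beta and two transversion
    rates beta each; tau is in beta*t units.
    """
    e4 = math.exp(-4.0 * tau)
    ek = math.exp(-2.0 * (kappa + 1.0) * tau)
    p_tv_each = 0.25 * (1.0 - e4)
    p_ts = 0.25 + 0.25 * e4 - 0.5 * ek
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    return p_same, p_ts, p_tv_each


def evolve_k2p(seq: str, tau: float, kappa: float, seed: int) -> str:
    """Evolve a nucleotide sequence for total divergence ``tau`` under K2P.

    Sites evolve independently; transitions occur at rate kappa*beta and each
    of the two transversions at rate beta, with tau = beta*t.  The expected
    fraction of transversion differences from the input is Q(tau).  Coding
    validity is *not* preserved: internal stops may appear, which is fine
    because only third positions of four-fold families are read downstream.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if not np.isin(arr, np.frombuffer(b"ACGT", dtype="S1")).all():
        raise ValueError("sequence must be over {A,C,G,T}")
    p_same, p_ts, p_tv = _k2p_outcome_probs(tau, kappa)
    rng = np.random.default_rng(seed)
    u = rng.random(arr.size)
    # outcome codes: 0 same, 1 transition, 2 first transversion, 3 second
    outcome = np.select(
        [u < p_same, u < p_same + p_ts, u < p_same + p_ts + p_tv],
        [0, 1, 2],
        default=3,
    )
    out = arr.copy()
    ts_map = {b: _TS_PARTNER[b] for b in _BASES}
    for base in _BASES:
        mask = arr == base.encode()
        out[mask & (outcome == 1)] = ts_map[base].encode()
        out[mask & (outcome == 2)] = _TV_PARTNERS[base][0].encode()
        out[mask & (outcome == 3)] = _TV_PARTNERS[base][1].encode()
    return out.tobytes().decode()


def simulate_ancestral_genes(config: SimulationConfig) -> dict[str, str]:
    """Ancestral CDS set: ATG start, stop-codon end, no internal stops.

    Gene ids are ``g0001``...; each sequence has config.codons_per_gene codons.
    Per-gene RNG streams are derived by hashing the gene id with the root
    seed, so individual genes are reproducible independent of order.
    """
    width = max(4, len(str(config.n_genes)))
    genes: dict[str, str] = {}
    internal = config.codons_per_gene - 2
    for i in range(config.n_genes):
        gid = f"g{i + 1:0{width}d}"
        rng = np.random.default_rng(_derive_seed(config.seed, "ancestral", gid))
        codons = rng.choice(len(_SENSE_CODONS), size=internal)
        body = "".join(_SENSE_CODONS[c] for c in codons)
        stop = _STOPS[rng.integers(len(_STOPS))]
        genes[gid] = "ATG" + body + stop
    return genes


# ---------------------------------------------------------------------------
# genome history


@dataclass
class _Lineage:
    uid: str          # e.g. "focal", "focal.sg2", "og1"
    genome: str       # "focal" or "og<k>"
    path: tuple[str, ...]   # branch choices, one entry per event experienced
    depth: float      # per-lineage time before present at which seqs are current
    seqs: dict[str, str] = field(default_factory=dict)
    frozen: bool = False  # outgroups receive no further events


def _evolve_lineage_to(lin: _Lineage, depth: float, config: SimulationConfig) -> None:
    branch = lin.depth - depth
    if branch < 0:
        raise RuntimeError("events must be processed deepest-first")
    if branch == 0:
        return
    for gid in lin.seqs:
        seed = _derive_seed(config.seed, "branch", gid, lin.uid, f"{lin.depth:.12g}")
        lin.seqs[gid] = evolve_k2p(lin.seqs[gid], branch, config.kappa, seed)
    lin.depth = depth


def build_genome_set(config: SimulationConfig) -> GenomeSet:
    """Run the event history and emit genomes, homology hits and truth.

    Events are applied deepest-first.  A speciation clones the current focal
    lineage set into a new outgroup genome that then evolves undisturbed to
    the present; a WGD multiplies every focal lineage into ``copies``
    subgenome copies, each of which independently loses each gene with
    probability ``loss_prob``.  Collinear gene order is preserved within
    chromosomes apart from losses.
    """
    if not any(e.kind == "wgd" for e in config.events):
        raise ValueError("config must contain at least one wgd event")
    ancestral = simulate_ancestral_genes(config)
    root_depth = config.events[0].tau / 2.0
    focal = [_Lineage("focal", "focal", (), root_depth, dict(ancestral))]
    done: list[_Lineage] = []
    n_outgroups = 0
    event_tau: list[float] = []

    for ei, event in enumerate(config.events):
        depth = event.tau / 2.0
        event_tau.append(event.tau)
        for lin in focal:
            _evolve_lineage_to(lin, depth, config)
        if event.kind == "speciation":
            n_outgroups += 1
            og = f"og{n_outgroups}"
            for lin in focal:
                clone = _Lineage(
                    uid=lin.uid.replace("focal", og, 1),
                    genome=og,
                    path=lin.path + (f"e{ei}:split",),
                    depth=depth,
                    seqs=dict(lin.seqs),
                    frozen=True,
                )
                done.append(clone)
                lin.path = lin.path + (f"e{ei}:stay",)
        else:  # wgd
            new_focal: list[_Lineage] = []
            for lin in focal:
                for c in range(1, event.copies + 1):
                    uid = f"{lin.uid}.sg{c}"
                    seqs = {}
                    for gid, s in lin.seqs.items():
                        r = np.random.default_rng(_derive_seed(config.seed, "loss", gid, uid))
                        if r.random() >= config.loss_prob:
                            seqs[gid] = s
                    new_focal.append(_Lineage(
                        uid=uid,
                        genome="focal",
                        path=lin.path + (f"e{ei}:c{c}",),
                        depth=depth,
                        seqs=seqs,
                    ))
            focal = new_focal

    for lin in focal:
        _evolve_lineage_to(lin, 0.0, config)
    for lin in done:
        _evolve_lineage_to(lin, 0.0, config)
    lineages = focal + done

    if all(len(lin.seqs) == 0 for lin in focal):
        raise ValueError("zero retained genes in the focal genome after loss")

    genes, record_by_id = _lay_out_genes(lineages, config)
    truth_df = _pair_truth(lineages, event_tau)
    hits = _hit_table(truth_df, record_by_id, config)
    return GenomeSet(config=config, genes=genes, hits=hits,
                     truth=SimulationTruth(pairs=truth_df))


def _lay_out_genes(
    lineages: list[_Lineage], config: SimulationConfig
) -> tuple[dict[str, list[GeneRecord]], dict[str, GeneRecord]]:
    spacer = 500
    gene_len = 3 * config.codons_per_gene
    genomes: dict[str, list[GeneRecord]] = {}
    by_id: dict[str, GeneRecord] = {}
    anc_order = sorted({g for lin in lineages for g in lin.seqs})
    anc_chrom = {g: i // config.genes_per_chromosome + 1 for i, g in enumerate(anc_order)}
    anc_rank = {g: i % config.genes_per_chromosome for i, g in enumerate(anc_order)}
    for lin in sorted(lineages, key=lambda l: l.uid):
        chrom_prefix = lin.uid.replace(".", "_")
        per_chrom: dict[int, list[str]] = {}
        for gid in sorted(lin.seqs, key=lambda g: (anc_chrom[g], anc_rank[g])):
            per_chrom.setdefault(anc_chrom[gid], []).append(gid)
        records = genomes.setdefault(lin.genome, [])
        for chrom_i, gids in sorted(per_chrom.items()):
            chrom = f"{chrom_prefix}_chr{chrom_i}"
            for rank, gid in enumerate(gids):
                start = 1 + rank * (gene_len + spacer)
                rec = GeneRecord(
                    gene_id=f"{gid}_{lin.uid}",
                    genome=lin.genome,
                    chrom=chrom,
                    start=start,
                    end=start + gene_len - 1,
                    seq=lin.seqs[gid],
                )
                records.append(rec)
                by_id[rec.gene_id] = rec
    return genomes, by_id


def _pair_truth(lineages: list[_Lineage], event_tau: list[float]) -> pd.DataFrame:
    rows = []
    lins = sorted(lineages, key=lambda l: l.uid)
    for i, la in enumerate(lins):
        for lb in lins[i + 1:]:
            # first event at which the two branch paths differ = their split
            split_tau = None
            for pa, pb in zip(la.path, lb.path):
                if pa != pb:
                    split_tau = event_tau[int(pa.split(":")[0][1:])]
                    break
            if split_tau is None:
                raise RuntimeError("lineage pair with no splitting event")
            relation = "paralog" if la.genome == lb.genome else "ortholog"
            for gid in sorted(set(la.seqs) & set(lb.seqs)):
                rows.append((
                    f"{gid}_{la.uid}", f"{gid}_{lb.uid}",
                    relation, split_tau, expected_4dtv(split_tau),
                ))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "relation", "true_tau", "expected_4dtv"]
    )


def _hit_table(
    truth: pd.DataFrame, by_id: dict[str, GeneRecord], config: SimulationConfig
) -> pd.DataFrame:
    """Emulated all-vs-all protein hit table (tabular outfmt-6 flavor)."""
    rows = []
    for t in truth.itertuples(index=False):
        a, b = by_id[t.gene_a], by_id[t.gene_b]
        p_same, _, _ = _k2p_outcome_probs(t.true_tau, config.kappa)
        pident = round(100.0 * p_same, 2)
        rows.append((a.gene_id, b.gene_id, pident, config.codons_per_gene,
                     a.chrom, a.start, a.end, b.chrom, b.start, b.end))
    if config.decoys and rows:
        n_decoy = int(round(config.decoy_fraction * len(rows)))
        rng = np.random.default_rng(_derive_seed(config.seed, "decoys"))
        all_ids = sorted(by_id)
        true_pairs = {frozenset((r[0], r[1])) for r in rows}
        made = 0
        while made < n_decoy:
            a_id, b_id = (all_ids[j] for j in rng.integers(len(all_ids), size=2))
            if a_id == b_id or frozenset((a_id, b_id)) in true_pairs:
                continue
            a, b = by_id[a_id], by_id[b_id]
            pident = round(30.0 + 30.0 * rng.random(), 2)
            rows.append((a.gene_id, b.gene_id, pident, config.codons_per_gene,
                         a.chrom, a.start, a.end, b.chrom, b.start, b.end))
            made += 1
    return pd.DataFrame(rows, columns=[
        "qid", "sid", "pident", "length",
        "qchrom", "qstart", "qend", "schrom", "sstart", "send",
    ])


# ---------------------------------------------------------------------------
# output


def _atomic_write_text(path: os.PathLike | str, text: str) -> None:
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_genome_set(gs: GenomeSet, outdir: os.PathLike | str) -> dict[str, Path]:
    """Write FASTA (60-column wrap), GFF3, hits TSV and truth TSV; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for genome, records in sorted(gs.genes.items()):
        fa = outdir / f"{genome}.cds.fasta"
        seqrecs = [
            SeqRecord(Seq(r.seq), id=r.gene_id, description="")
            for r in records
        ]
        tmp = fa.with_name(fa.name + ".tmp")
        with open(tmp, "w") as fh:
            SeqIO.write(seqrecs, fh, "fasta")
        os.replace(tmp, fa)
        paths[f"fasta:{genome}"] = fa

        gff_lines = ["##gff-version 3"]
        for r in records:
            gff_lines.append(
                f"{r.chrom}\tpaleoploid\tgene\t{r.start}\t{r.end}\t.\t+\t.\tID={r.gene_id}"
            )
        gff = outdir / f"{genome}.gff3"
        _atomic_write_text(gff, "\n".join(gff_lines) + "\n")
        paths[f"gff3:{genome}"] = gff

    hits_path = outdir / "hits.tsv"
    _atomic_write_text(hits_path, gs.hits.to_csv(sep="\t", index=False))
    paths["hits"] = hits_path
    truth_path = outdir / "truth.tsv"
    gs.truth.to_tsv(truth_path)
    paths["truth"] = truth_path
    return paths


def fig1b_scenario(
    n_genes: int = 160,
    codons_per_gene: int = 240,
    genes_per_chromosome: int = 10,
    loss_prob: float = 0.05,
    seed: int = 0,
    paralog_4dtv: float = 0.042,
    ortholog_4dtv: tuple[float, float] = (0.27, 0.16),
    subgenomes: int = 3,
    **kwargs,
) -> SimulationConfig:
    """Three-level scenario behind the observed 4dTv distribution.

    Two speciations split off outgroups at the deep ortholog levels (default
    4dTv 0.27 and 0.16), then one hybridization/WGD emits three subgenome
    copies at the shallow paralog level (default 4dTv 0.042).
    """
    deep, mid = sorted(ortholog_4dtv, reverse=True)
    events = (
        DivergenceEvent("speciation", tau_for_target_4dtv(deep)),
        DivergenceEvent("speciation", tau_for_target_4dtv(mid)),
        DivergenceEvent("wgd", tau_for_target_4dtv(paralog_4dtv), copies=subgenomes),
    )
    return SimulationConfig(
        n_genes=n_genes,
        codons_per_gene=codons_per_gene,
        genes_per_chromosome=genes_per_chromosome,
        loss_prob=loss_prob,
        seed=seed,
        events=events,
        **kwargs,
    )
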