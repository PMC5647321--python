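"""Collinear anchor chaining into syntenic blocks.

Homology hits between two annotated genomes are reduced to *anchors* carrying
gene-order ranks along their chromosomes, and chained by dynamic programming
within each chromosome pair: a chain must advance ranks strictly in both
genomes (ascending, or descending in genome B for inverted blocks), rank gaps
are bounded and penalized, and maximal-scoring non-overlapping chains are
extracted greedily.  Per-pair 4dTv values are then aggregated to a per-block
value (median by default).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pandas as pd

__all__ = [
    "Anchor",
    "ChainParams",
    "SyntenicBlock",
    "gene_ranks_from_gff",
    "load_hits",
    "chain_anchors",
    "chain_all",
    "block_4dtv",
    "blocks_to_frame",
]


@dataclass(frozen=True)
class Anchor:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.rank_a < 0 or self.rank_b < 0:
            raise ValueError("ranks must be >= 0")


@dataclass(frozen=True)
class ChainParams:
    max_gap: int = 10
    min_anchors: int = 5
    gap_penalty: float = 1.0
    anchor_score: float = 10.0

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")


@dataclass
class SyntenicBlock:
    anchors: tuple[Anchor, ...]
    orientation: str  # "same" | "inverted"
    chrom_a: str
    chrom_b: str
    block_score: float
    block_4dtv: float | None = None

    def __len__(self) -> int:
        return len(self.anchors)


def gene_ranks_from_gff(gff_path: str | Path) -> dict[str, tuple[str, int]]:
    """gene id -> (chromosome, gene-order rank) from a GFF3 annotation.

    Ranks are 0-based indices of coordinate-sorted genes within each
    chromosome.
    """
    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="error")
    genes = sorted(
        ((f.seqid, f.start, f.id) for f in db.features_of_type("gene")),
        key=lambda t: (t[0], t[1], t[2]),
    )
    ranks: dict[str, tuple[str, int]] = {}
    counter: dict[str, int] = {}
    for seqid, _start, gid in genes:
        r = counter.get(seqid, 0)
        ranks[gid] = (seqid, r)
        counter[seqid] = r + 1
    return ranks


def load_hits(
    hit_tsv: str | Path,
    gff_a: str | Path,
    gff_b: str | Path,
    strict: bool = True,
) -> list[Anchor]:
    """Turn a tabular hit table into rank-bearing anchors.

    Gene ranks come from the annotations, not from base-pair positions in the
    hit rows.  Duplicate (query, subject) rows keep the highest score; with
    ``strict`` (default) an id absent from both annotations raises, otherwise
    the row is dropped (useful when the table spans more genome pairs than
    the two annotations given).
    """
    ranks = gene_ranks_from_gff(gff_a)
    ranks_b = gene_ranks_from_gff(gff_b)
    for gid, cr in ranks_b.items():  # gff_a may equal gff_b (self-comparison)
        ranks.setdefault(gid, cr)
    hits = pd.read_csv(hit_tsv, sep="\t")
    best: dict[tuple[str, str], Anchor] = {}
    for row in hits.itertuples(index=False):
        qid, sid, score = str(row.qid), str(row.sid), float(row.pident)
        if qid not in ranks or sid not in ranks:
            if strict:
                missing = qid if qid not in ranks else sid
                raise ValueError(f"hit id {missing!r} not found in the annotations")
            continue
        ca, ra = ranks[qid]
        cb, rb = ranks[sid]
        key = (qid, sid)
        if key not in best or score > best[key].score:
            best[key] = Anchor(qid, sid, ca, cb, ra, rb, score)
    return list(best.values())


def _collapse_tandem(anchors: Sequence[Anchor]) -> list[Anchor]:
    """Per rank on either axis keep only the best-scoring anchor."""
    by_a: dict[int, Anchor] = {}
    for a in sorted(anchors, key=lambda x: (-x.score, x.rank_a, x.rank_b)):
        by_a.setdefault(a.rank_a, a)
    by_b: dict[int, Anchor] = {}
    for a in sorted(by_a.values(), key=lambda x: (-x.score, x.rank_a, x.rank_b)):
        by_b.setdefault(a.rank_b, a)
    return sorted(by_b.values(), key=lambda x: (x.rank_a, x.rank_b))


def _best_chain(
    anchors: list[Anchor], params: ChainParams, orientation: str
) -> tuple[float, list[Anchor]] | None:
    """Highest-scoring valid chain in one orientation (DP over sorted anchors)."""
    if not anchors:
        return None
    sign = 1 if orientation == "same" else -1
    order = sorted(anchors, key=lambda x: (x.rank_a, sign * x.rank_b))
    n = len(order)
    score = [params.anchor_score] * n
    prev = [-1] * n
    for j in range(n):
        aj = order[j]
        for i in range(j):
            ai = order[i]
            da = aj.rank_a - ai.rank_a
            db = sign * (aj.rank_b - ai.rank_b)
            if da < 1 or db < 1:
                continue
            if da - 1 > params.max_gap or db - 1 > params.max_gap:
                continue
            s = score[i] + params.anchor_score - params.gap_penalty * ((da - 1) + (db - 1))
            if s > score[j]:
                score[j] = s
                prev[j] = i
    best = max(score)
    candidates = []
    for j in range(n):
        if score[j] == best:
            chain = []
            k = j
            while k != -1:
                chain.append(order[k])
                k = prev[k]
            chain.reverse()
            candidates.append(chain)
    # ties: earliest start on genome A wins, then the longer chain
    chain = min(candidates, key=lambda c: (c[0].rank_a, -len(c), c[0].rank_b))
    return best, chain


def chain_anchors(anchors: Sequence[Anchor], params: ChainParams | None = None) -> list[SyntenicBlock]:
    """Chain anchors of one chromosome pair into syntenic blocks.

    Both orientations are attempted; the best chain (score, then forward
    orientation, then earliest start) is extracted, its anchors removed, and
    the process repeats.  Chains shorter than ``min_anchors`` are discarded
    but still consume their anchors, keeping extraction deterministic.
    """
    params = params or ChainParams()
    chroms = {(a.chrom_a, a.chrom_b) for a in anchors}
    if len(chroms) > 1:
        raise ValueError("chain_anchors expects anchors from a single chromosome pair")
    remaining = _collapse_tandem(anchors)
    blocks: list[SyntenicBlock] = []
    while remaining:
        options = []
        for orientation in ("same", "inverted"):
            res = _best_chain(remaining, params, orientation)
            if res is not None:
                score, chain = res
                options.append((score, orientation == "same", chain))
        if not options:
            break
        score, is_same, chain = max(
            options, key=lambda o: (o[0], o[1], -o[2][0].rank_a, len(o[2]))
        )
        if len(chain) >= params.min_anchors:
            blocks.append(SyntenicBlock(
                anchors=tuple(chain),
                orientation="same" if is_same else "inverted",
                chrom_a=chain[0].chrom_a,
                chrom_b=chain[0].chrom_b,
                block_score=score,
            ))
        used = {(a.rank_a, a.rank_b) for a in chain}
        remaining = [a for a in remaining if (a.rank_a, a.rank_b) not in used]
    return blocks


def chain_all(anchors: Sequence[Anchor], params: ChainParams | None = None) -> list[SyntenicBlock]:
    """Partition anchors by chromosome pair and chain each partition."""
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.chrom_a, a.chrom_b), []).append(a)
    blocks: list[SyntenicBlock] = []
    for key in sorted(groups):
        blocks.extend(chain_anchors(groups[key], params))
    return blocks


def block_4dtv(
    block: SyntenicBlock,
    pair_values: Mapping[tuple[str, str], float],
    aggregate: str = "median",
) -> SyntenicBlock:
    """Attach the aggregated per-pair 4dTv of a block's anchors.

    Pair values are looked up in either gene order; undefined (missing or
    NaN) pairs are skipped.  A block with no defined pair value gets
    ``block_4dtv = None`` and is excluded from dating downstream.
    """
    values = []
    for a in block.anchors:
        v = pair_values.get((a.gene_a, a.gene_b))
        if v is None:
            v = pair_values.get((a.gene_b, a.gene_a))
        if v is not None and v == v:  # filter NaN
            values.append(v)
    if not values:
        return replace_block(block, block_4dtv=None)
    if aggregate == "median":
        agg = statistics.median(values)
    elif aggregate == "mean":
        agg = statistics.fmean(values)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return replace_block(block, block_4dtv=agg)


def replace_block(block: SyntenicBlock, **changes) -> SyntenicBlock:
    return replace(block, **changes)


def blocks_to_frame(blocks: Sequence[SyntenicBlock]) -> pd.DataFrame:
    rows = [
        (i + 1, b.chrom_a, b.chrom_b, b.orientation, len(b), b.block_score, b.block_4dtv)
        for i, b in enumerate(blocks)
    ]
    return pd.DataFrame(rows, columns=[
        "block_id", "chrom_a", "chrom_b", "orientation",
        "n_anchors", "block_score", "block_4dtv",
    ])
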