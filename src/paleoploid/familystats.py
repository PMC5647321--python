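"""Gene-family statistics: domain over-representation, expansion profiles,
and qPCR relative-expression fold changes.

Over-representation of a protein domain in a focal genome against a
multi-genome background is tested with the one-sided (upper-tail)
hypergeometric test: drawing the focal genome's n genes without replacement
from the N genes of the union, what is the probability of seeing >= k genes
carrying the domain when K genes in the union carry it?

Expansion profiles summarize within-family pairwise amino-acid p-distances;
a recently expanded family (e.g. after polyploidization) shows a mass of
near-zero distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .codonstats import compute_aa_distance, _make_aligner

__all__ = [
    "DomainCountTable",
    "ExpansionProfile",
    "CtMeasurement",
    "hypergeometric_enrichment",
    "build_domain_table",
    "enrich_all_domains",
    "expansion_profile",
    "fold_change_ddct",
]


@dataclass(frozen=True)
class DomainCountTable:
    """Counts for one domain: focal genome draw vs the genome union.

    focal_with (k) <= focal_total (n); background_with (K) and
    background_total (N) describe the union, which by default includes the
    focal genome's own genes (one-set-vs-union convention).
    """

    focal_with: int
    focal_total: int
    background_with: int
    background_total: int

    def __post_init__(self) -> None:
        k, n, K, N = (self.focal_with, self.focal_total,
                      self.background_with, self.background_total)
        if min(k, n, K, N) < 0:
            raise ValueError("counts must be non-negative")
        if k > n or k > K:
            raise ValueError("focal_with cannot exceed focal_total or background_with")
        if n > N or K > N:
            raise ValueError("focal_total and background_with cannot exceed background_total")


@dataclass(frozen=True)
class ExpansionProfile:
    family_id: str
    pairwise_distances: tuple[float, ...]
    bin_edges: np.ndarray
    histogram: np.ndarray
    low_divergence_fraction: float


@dataclass(frozen=True)
class CtMeasurement:
    target_ct: float
    reference_ct: float
    control_target_ct: float
    control_reference_ct: float

    def __post_init__(self) -> None:
        for v in (self.target_ct, self.reference_ct,
                  self.control_target_ct, self.control_reference_ct):
            if not (np.isfinite(v) and v > 0):
                raise ValueError("Ct values must be finite and positive")


def hypergeometric_enrichment(table: DomainCountTable) -> float:
    """Upper-tail hypergeometric p-value P[X >= k] for over-representation."""
    k, n, K, N = (table.focal_with, table.focal_total,
                  table.background_with, table.background_total)
    return float(hypergeom.sf(k - 1, N, K, n))


def build_domain_table(
    annotations: pd.DataFrame,
    focal_genome: str,
    domain: str,
    background_genomes: Sequence[str] | None = None,
) -> DomainCountTable:
    """Count table from a (gene_id, genome_id, domain_accession) annotation.

    A gene counts as domain-positive if any of its rows carries the domain.
    The sampling universe is the union of the focal genome and the background
    genomes (all non-focal genomes in the table unless ``background_genomes``
    narrows them): the focal genome's n genes are treated as a draw without
    replacement from that union.
    """
    required = {"gene_id", "genome_id", "domain_accession"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    genes = annotations.groupby(["genome_id", "gene_id"])["domain_accession"] \
                       .apply(lambda s: domain in set(s))
    genomes = genes.index.get_level_values("genome_id")
    if focal_genome not in genomes:
        raise ValueError(f"no genes annotated for focal genome {focal_genome!r}")
    focal = genes.xs(focal_genome, level="genome_id")
    if background_genomes is None:
        universe = genes
    else:
        keep = set(background_genomes) | {focal_genome}
        universe = genes[genomes.isin(keep)]
    return DomainCountTable(
        focal_with=int(focal.sum()),
        focal_total=int(focal.size),
        background_with=int(universe.sum()),
        background_total=int(universe.size),
    )


def enrich_all_domains(
    annotations: pd.DataFrame,
    focal_genome: str,
    domains: Sequence[str] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-domain enrichment scan; optional Benjamini-Hochberg adjustment."""
    if domains is None:
        domains = sorted(annotations["domain_accession"].unique())
    rows = []
    for dom in domains:
        t = build_domain_table(annotations, focal_genome, dom)
        rows.append((dom, t.focal_with, t.focal_total,
                     t.background_with, t.background_total,
                     hypergeometric_enrichment(t)))
    out = pd.DataFrame(rows, columns=["domain", "k", "n", "K", "N", "p_value"])
    if fdr and len(out):
        out["p_adjusted"] = false_discovery_control(out["p_value"], method="bh")
    return out


def expansion_profile(
    family_members: Mapping[str, str],
    family_id: str = "family",
    bin_width: float = 0.02,
    low_threshold: float = 0.05,
    aligned: bool = False,
) -> ExpansionProfile:
    """All within-family pairwise amino-acid p-distances, binned.

    ``family_members`` maps member id to protein sequence.  Unless
    ``aligned``, each pair is globally aligned (BLOSUM62, affine gaps) before
    the p-distance is taken over gap-free columns.  The low-divergence
    fraction is the share of pairs below ``low_threshold`` — the recent-
    expansion signal.
    """
    if len(family_members) < 2:
        raise ValueError("a family needs at least 2 members")
    aligner = _make_aligner(11.0, 1.0)
    dists = []
    for (ia, pa), (ib, pb) in combinations(sorted(family_members.items()), 2):
        if aligned:
            ga, gb = pa, pb
        else:
            aln = aligner.align(pa, pb)[0]
            ga, gb = str(aln[0]), str(aln[1])
        d = compute_aa_distance(ga, gb)
        if d.defined:
            dists.append(d.p_distance)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    hist, _ = np.histogram(dists, bins=edges)
    low = float(np.mean([d < low_threshold for d in dists])) if dists else 0.0
    return ExpansionProfile(family_id, tuple(dists), edges, hist, low)


def fold_change_ddct(m: CtMeasurement) -> float:
    """Relative expression by 2^-ddCt from target/reference Ct values.

    dCt_treat = target - reference; dCt_control likewise; the fold change is
    2 ** -(dCt_treat - dCt_control).
    """
    ddct = (m.target_ct - m.reference_ct) - (m.control_target_ct - m.control_reference_ct)
    return float(2.0 ** (-ddct))
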