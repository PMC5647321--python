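"""Codon-aware pair alignment and 4dTv / amino-acid distance statistics.

4dTv — the fraction of four-fold degenerate third codon positions at which a
gene pair differs by a transversion — is a slowly saturating proxy for
neutral divergence (it plateaus at 0.5).  Here a pairwise codon alignment is
built by globally aligning the translated proteins and back-translating, and
four-fold sites are counted under a conservative convention: both codons of
the pair must belong to a four-fold family and agree at their first two
positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "CodonPairAlignment",
    "FourDTvResult",
    "AADistance",
    "align_pair_codon_aware",
    "identify_fourfold_sites",
    "classify_substitution",
    "compute_4dtv",
    "compute_aa_distance",
    "fourdtv_table",
]

# codon families whose third position is fully degenerate under the standard code
FOURFOLD_PREFIXES = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
)
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class CodonPairAlignment:
    """Two in-frame, gap-aligned CDS; gaps only in whole-codon runs."""

    id_a: str
    id_b: str
    aln_a: str
    aln_b: str

    def __post_init__(self) -> None:
        if len(self.aln_a) != len(self.aln_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.aln_a) % 3 != 0:
            raise ValueError("aligned length must be divisible by 3")
        allowed = set("ACGTN-")
        if (set(self.aln_a.upper()) | set(self.aln_b.upper())) - allowed:
            raise ValueError("alignment contains characters outside {A,C,G,T,N,-}")

    def codons(self) -> Iterable[tuple[int, str, str]]:
        """Yield (column index of codon start, codon_a, codon_b)."""
        a, b = self.aln_a.upper(), self.aln_b.upper()
        for i in range(0, len(a), 3):
            yield i, a[i:i + 3], b[i:i + 3]


@dataclass(frozen=True)
class FourDTvResult:
    n_4d_sites: int
    n_transversions: int
    n_transitions: int
    fourdtv: float | None  # None when no four-fold sites exist

    @property
    def defined(self) -> bool:
        return self.fourdtv is not None


@dataclass(frozen=True)
class AADistance:
    p_distance: float | None
    poisson_corrected: float | None  # None at p = 1 (log undefined) or no columns

    @property
    def defined(self) -> bool:
        return self.p_distance is not None


@lru_cache(maxsize=4)
def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _translate(cds: str) -> str:
    n = len(cds) - len(cds) % 3  # drop an incomplete trailing codon
    return str(Seq(cds[:n]).translate())


def align_pair_codon_aware(
    cds_a: str,
    cds_b: str,
    id_a: str = "a",
    id_b: str = "b",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> CodonPairAlignment:
    """Protein-guided codon alignment of two CDS.

    Both CDS are translated (standard code; internal stops become '*' and are
    aligned like any residue), the proteins are globally aligned with BLOSUM62
    and affine gap costs, and the protein alignment is back-translated so gaps
    appear in whole codons.  Of co-optimal alignments the aligner's first
    (leftmost-gap) alignment is used, deterministically.
    """
    if not cds_a or not cds_b:
        raise ValueError("empty sequence")
    cds_a = cds_a.upper()
    cds_b = cds_b.upper()
    prot_a, prot_b = _translate(cds_a), _translate(cds_b)
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(prot_a, prot_b)[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])

    out_a, out_b = [], []
    ia = ib = 0
    for ra, rb in zip(gapped_a, gapped_b):
        if ra == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if rb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib:3 * ib + 3])
            ib += 1
    return CodonPairAlignment(id_a, id_b, "".join(out_a), "".join(out_b))


def identify_fourfold_sites(aln: CodonPairAlignment) -> list[int]:
    """Alignment column indices (third codon positions) of four-fold sites.

    A column qualifies iff neither codon contains a gap or ambiguity, both
    codons are in a four-fold degenerate family, and the first two codon
    positions match between the pair.
    """
    sites = []
    for col, ca, cb in aln.codons():
        if set(ca + cb) - set("ACGT"):
            continue
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            sites.append(col + 2)
    return sites


def classify_substitution(base_a: str, base_b: str) -> str:
    """'identical', 'transition' (A<->G, C<->T) or 'transversion'."""
    a, b = base_a.upper(), base_b.upper()
    if a not in "ACGT" or b not in "ACGT" or len(a) != 1 or len(b) != 1:
        raise ValueError(f"ambiguous or invalid bases: {base_a!r}, {base_b!r}")
    if a == b:
        return "identical"
    if {a, b} <= _PURINES or {a, b} <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def compute_4dtv(aln: CodonPairAlignment, correct: bool = False) -> FourDTvResult:
    """Transversion fraction over the pair's four-fold degenerate sites.

    The raw proportion is reported by default.  With ``correct=True`` a
    Kimura-style multiple-hit correction -ln(1 - 2q)/2 is applied (undefined
    at q >= 0.5, reported as None).
    """
    n_sites = n_tv = n_ts = 0
    for col in identify_fourfold_sites(aln):
        n_sites += 1
        kind = classify_substitution(aln.aln_a[col], aln.aln_b[col])
        if kind == "transversion":
            n_tv += 1
        elif kind == "transition":
            n_ts += 1
    if n_sites == 0:
        return FourDTvResult(0, 0, 0, None)
    q: float | None = n_tv / n_sites
    if correct:
        q = None if q >= 0.5 else -0.5 * math.log(1.0 - 2.0 * q)
    return FourDTvResult(n_sites, n_tv, n_ts, q)


def compute_aa_distance(protein_aln_a: str, protein_aln_b: str) -> AADistance:
    """p-distance over gap-free columns and its Poisson correction -ln(1-p)."""
    if len(protein_aln_a) != len(protein_aln_b):
        raise ValueError("aligned proteins must have equal length")
    n = diff = 0
    for ra, rb in zip(protein_aln_a.upper(), protein_aln_b.upper()):
        if ra == "-" or rb == "-":
            continue
        n += 1
        if ra != rb:
            diff += 1
    if n == 0:
        return AADistance(None, None)
    p = diff / n
    corrected = None if p >= 1.0 else -math.log(1.0 - p)
    return AADistance(p, corrected)


def fourdtv_table(
    cds: dict[str, str],
    pairs: Iterable[tuple[str, str]],
    correct: bool = False,
) -> pd.DataFrame:
    """Per-pair 4dTv and protein p-distance for a list of gene pairs.

    Each pair is codon-aligned via its translated proteins; pairs whose ids
    are missing from ``cds`` raise.  fourdtv is NaN where a pair has no
    four-fold degenerate sites.
    """
    rows = []
    for id_a, id_b in pairs:
        if id_a not in cds:
            raise KeyError(f"CDS for {id_a!r} not found")
        if id_b not in cds:
            raise KeyError(f"CDS for {id_b!r} not found")
        aln = align_pair_codon_aware(cds[id_a], cds[id_b], id_a, id_b)
        res = compute_4dtv(aln, correct=correct)
        prot_a = "".join(
            str(Seq(aln.aln_a[i:i + 3]).translate()) if "-" not in aln.aln_a[i:i + 3] else "-"
            for i in range(0, len(aln.aln_a), 3)
        )
        prot_b = "".join(
            str(Seq(aln.aln_b[i:i + 3]).translate()) if "-" not in aln.aln_b[i:i + 3] else "-"
            for i in range(0, len(aln.aln_b), 3)
        )
        dist = compute_aa_distance(prot_a, prot_b)
        rows.append((
            id_a, id_b, res.n_4d_sites, res.n_transversions,
            res.fourdtv if res.defined else float("nan"),
            dist.p_distance if dist.defined else float("nan"),
        ))
    return pd.DataFrame(rows, columns=[
        "id_a", "id_b", "n_4d_sites", "n_transversions", "fourdtv", "p_distance",
    ])
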