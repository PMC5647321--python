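# paleoploid

Dating polyploidization and speciation events from the divergence of
syntenic gene pairs — with a synthetic allopolyploid genome simulator, so
the whole analysis is testable end to end without external data.

## The problem

An allohexaploid genome (three subgenomes merged by hybridization/
polyploidization) keeps a record of its history in its duplicated genes.
For every gene pair in a syntenic block, the **4dTv** statistic — the
fraction of four-fold degenerate third codon positions that differ by a
transversion — measures near-neutral divergence and saturates only at 0.5.
Paralog pairs created by a whole-genome duplication (WGD) share one
divergence level; ortholog pairs to outgroup genomes sit at older levels.
The 4dTv distribution over blocks is therefore multimodal, one mode per
event, and a two-lineage molecular clock

    rate = x_anchor / (2 * t_anchor),      t_peak = x_peak / (2 * rate)

converts mode positions to ages in Mya.  Typical anchor values for a grass
hexaploid: ortholog peaks at 4dTv ≈ 0.27 and 0.16 (≈ 46.7 and 27.9 Mya) and
a paralog peak at ≈ 0.042 (≈ 7 Mya, dating the polyploidization).

## What's in the package

| module                   | what it does                                                            |
| ------------------------ | ----------------------------------------------------------------------- |
| `paleoploid.simulate`    | K2P sequence evolution; WGD/speciation event histories; FASTA/GFF3/hit-table/truth output |
| `paleoploid.codonstats`  | protein-guided codon alignment, four-fold site identification, 4dTv, amino-acid distances |
| `paleoploid.synteny`     | gene-rank anchors from GFF3, DP chaining into (inverted) collinear blocks, block-median 4dTv |
| `paleoploid.dating`      | Gaussian KDE of 4dTv values, prominence-based peak detection, clock calibration and dating |
| `paleoploid.familystats` | upper-tail hypergeometric domain enrichment, family expansion profiles, 2^-ddCt fold change |
| `paleoploid.pipeline`    | orchestrated simulate → 4dTv → chain → date (→ enrich) runs with a checksummed manifest |

The `analysis/` directory holds the numbered drivers that tell the story in
order; `paleoploid` is also a CLI (`simulate`, `fourdtv`, `chain`, `date`,
`enrich`, `run`).

## Worked example

```sh
python analysis/01_simulate_genomes.py
python analysis/02_pair_divergence.py
python analysis/03_chain_synteny.py
python analysis/04_date_events.py
python analysis/05_family_statistics.py
```

simulates a hexaploid (three subgenomes from one WGD at expected 4dTv
0.042) plus two outgroups (0.16, 0.27), then recovers that structure:

```
computed 4dTv for 1513 pairs (0 undefined) -> pairs_4dtv.tsv
  ortholog expected 0.160: observed mean 0.1618 over 458 pairs
  ortholog expected 0.270: observed mean 0.2741 over 618 pairs
  paralog  expected 0.042: observed mean 0.0413 over 437 pairs
chained 1513 anchors into 160 blocks (median size 10)
KDE over 160 block values, bandwidth 0.0324
clock: 2.8908e-03 4dTv/My per lineage from anchor (0.27, 46.7 Mya)
  peak at 4dTv 0.041 -> 7.1 Mya
  peak at 4dTv 0.159 -> 27.6 Mya
  peak at 4dTv 0.276 -> 47.7 Mya
```

Reading the output: the per-pair means sit on the three configured
divergence levels; chaining recovers one block per homologous chromosome
pair; the KDE shows three modes whose clock-converted ages bracket the
configured history (the paralog mode at 0.041 dates the simulated
polyploidization to ~7 Mya under the deep ortholog anchor).  Tables land
under `results/`.

The same thing as a library:

```python
from paleoploid.pipeline import paralog_peak_experiment
res = paralog_peak_experiment(seed=1)   # one WGD at expected 4dTv 0.042
print(res["peak_position"])             # ~0.040, within ±0.01 of the target
```

## Notes

Design decisions, model assumptions, and what the simulations do *not*
demonstrate are documented in [docs/methods.md](docs/methods.md).
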