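# bsplice

Gene expression and alternative splicing during human B-cell differentiation,
as a tested, reusable analysis pipeline. The biological setting: as activated
B cells differentiate into antibody-secreting plasmablasts/plasma cells (PB,
PC) or resting memory B cells (MBC), the secretory machinery — in particular
the COPII coat (SEC23/24, SEC13/31, SEC16, KLHL12) that exports cargo from
the ER — is remodeled both by transcription and by alternative splicing.
Some splice events destroy the reading frame and route the transcript into
nonsense-mediated decay (AS-NMD), lowering protein output; others preserve
the frame and swap functional domains. A two-stage co-expression screen asks
which transcription factor could drive the MBC-specific expression of COPII
genes that are *not* splice-regulated.

The package implements every analysis stage over synthetic data that
emulates the study design (a 4-condition × 3-replicate B-cell panel and a
17-sample tissue panel), so the whole pipeline is exercisable and testable
without any sequencing download.

## What it computes

**PSI and differential splicing.** For a splice event with
inclusion-junction reads $I$, skipping-junction reads $S$ and effective
junction counts $l_I, l_S$ (2 vs 1 for exon skipping, 1 vs 1 otherwise):

$$\mathrm{PSI} = \frac{I/l_I}{I/l_I + S/l_S}$$

Differential splicing between groups uses a Welch t test on replicate PSI
values with the gates $p < 0.001$ and $|\Delta\mathrm{PSI}| > 0.4$, followed
by event-type breakdowns (SE/RI/A5SS/A3SS) and a direction statistic (the
fraction of significant events less included in a focal cell type).

**Differential expression.** Median-of-ratios normalization, then a per-gene
Welch t test on $\log_2(\text{normalized}+1)$ with Benjamini–Hochberg
correction and the gates $P_{adj} < 0.001$, $|\log_2 FC| > 0.5$; plus
hypergeometric gene-set enrichment (BH, FDR < 0.05), directional gene-set
summaries, and sample PCA.

**Splice-event consequences.** Events are applied to transcript models
(cassette in/out, intron retained, alternative splice site), the variant ORF
is re-scanned, and each isoform is classified: frame-preserving,
frameshift-NMD (PTC ≥ 50 nt upstream of the last exon–exon junction),
frameshift escaping NMD via a stop in the last exon, or no-ORF (with an
optional low-confidence downstream-AUG rescue). Annotated protein domains
that are deleted or stranded downstream of the new stop are reported lost.
The built-in toy annotation reproduces the exemplars: a 116-nt exon whose
skipping triggers NMD (SEC24C-like), a 296-nt poison exon (SEC24D-like), a
99 + 187 nt cassette pair whose joint skipping escapes NMD and truncates 3
of 6 kelch repeats (KLHL12-like), a 50-nt exon coupled to an alternative
start (SEC31A-like), two frame-preserving cassettes (PICALM-like), and a
dual-start / alternative-3'SS transcript (NERF/ELF2-like).

**TF screen.** Candidates from TF gene sets are Pearson-correlated with the
target genes (SEC24B, CUL3, CSNK1D stand-ins) on the discovery panel; TFs
with $r > 0.9$ for all targets are validated on the tissue panel by the mean
of per-target $r$ and $p$ (two-sided, from $t = r\sqrt{(n-2)/(1-r^2)}$) and
ranked.

## Worked example

Run the numbered drivers from the repository root:

```bash
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_differential_splicing.py
python analysis/04_splice_consequences.py
python analysis/05_tf_screen.py
```

Output of the splicing and screen stages (seed 1):

```
significant events (p<0.001, |dPSI|>0.4): 26 of 200
planted shifts > 0.4 recovered: 26/27
breakdown: SE: 21 (80.8%), RI: 1 (3.8%), A5SS: 2 (7.7%), A3SS: 2 (7.7%)
...
SEC24C_t1 SE_SEC24C_e11 [skipping] delta=-116 -> frameshift-NMD
KLHL12_t1 SE_KLHL12_e11 [skipping] delta=-286 -> frameshift-escape-alt-terminus,
    lost domains: kelch_4,kelch_5,kelch_6
...
discovery at r > 0.9: 1 TFs pass for >=1 target, 1 for all 3
validation across 17 tissues -> top hit: TF0000 (mean r = 0.994, mean p = 3.17e-15)
planted TF recovered at rank 1
```

Reading this: of 200 simulated events, the 26 called significant are almost
exactly the 27 planted with a true MBC shift beyond the 0.4 gate, and the
type breakdown mirrors the SE-dominated event mix. The consequence calls
reproduce the exemplar logic (−116 shifts the frame and triggers NMD; the
−286 joint skip shifts the frame but the new stop lands in the last exon, so
it escapes NMD while deleting half the kelch repeats). In the screen, only
the planted TF survives the $r > 0.9$ intersection and it ranks first after
tissue validation.

The same stages are available as a CLI (`bsplice simulate|de|enrich|splice|
consequence|tfscreen|run`); `bsplice run` executes everything from one YAML
config and writes a `summary.json`.

## Layout

- `src/bsplice/` — the library: `synthetic`, `expression`, `splicing`,
  `consequence`, `screen`, `pipeline`, `io`, `cli`
- `analysis/` — numbered narrative drivers writing under `results/`
- `tests/` — pytest suite, including brute-force oracle checks for BH,
  hypergeometric tails, Pearson r/p and ORF scanning
- `docs/methods.md` — models, assumptions, parameter choices, limitations
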