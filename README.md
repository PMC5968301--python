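# spectyper

Open, tested tooling for **MALDI-TOF MS spectral typing of bacterial
isolates**: building custom main-spectral-profile (MSP) reference
libraries from replicate spectra, identifying unknowns on the 0–3
log-score scale with a replicate-consensus rubric, resolving strain-level
structure with the composite correlation index (CCI), and cross-checking
every identification against 16S rRNA taxonomy.

It targets collections — such as environmental or cleanroom culture
archives dominated by spore-forming *Bacillus* — where commercial
spectral databases are too clinically biased to be useful and a
laboratory must curate its own reference library, validating it against
the 16S gold standard.

## The method

**Database construction.** Each reference isolate is acquired in 8
biological replicates × 3 acquisition intervals. Spectra are smoothed
(Savitzky–Golay), baseline-subtracted (SNIP iterative clipping),
QC-screened (flat-line and cohort-outlier elimination) and peak-picked at
an SNR threshold. Peaks are clustered across replicates on the m/z axis;
only peaks present in **more than 75 %** of replicates survive, and an
entry requires **at least 10** contributing spectra. Every contributing
spectrum must score **> 2.7** against its own MSP.

**Identification.** An unknown's peak list is scored against each library
entry with the three-component composite

```
score = log10( 1000 · s_query · s_ref · s_int ),  clamped to [0, 3]
```

where `s_query` is the fraction of query peaks matched within a 2 Da
tolerance, `s_ref` the (frequency-weighted) fraction of reference peaks
matched, and `s_int` the non-negative Pearson correlation of matched-pair
intensities. A species-level call requires the **same top entry with
score ≥ 2.2 in at least 3 of 4 replicates**; anything less is reported as
unidentified / potentially novel.

**Strain resolution.** The CCI splits the 3,000–12,000 m/z range into 10
intervals, correlates two binned profiles interval-by-interval and
averages the non-negative correlations: 1 = identical, 0 = unrelated,
\> 0.9 = strong. MSP dendrograms use Euclidean distance with average
linkage (UPGMA).

**16S layer.** Percent identity by global alignment (terminal gaps
excluded); **≥ 98.7 %** to a type-strain reference is a species-level
call, **> 95 %** genus level; OTUs at 99 % similarity with
minimum-total-distance representatives; neighbor-joining trees.
Taxonomic groups — sets of species (e.g. the *B. pumilus* group) whose
16S genes are ≥ 99.9 % identical — are unresolvable at this layer and are
handled by a registry during concordance analysis.

## Worked example

Ten isolates of the *B. pumilus* taxonomic group with both a 16S call and
a MALDI-TOF hit ship with the package:

```python
from spectyper import concordance as C
from spectyper.datasets import pumilus_group_case_study

rows = pumilus_group_case_study()
records = [C.categorize(r.isolate_id, r.species_16s, r.identity_16s,
                        r.maldi_entry, r.log_score, threshold=2.2)
           for r in rows.itertuples()]
for r in records:
    print(f"{r.isolate_id:<14} {r.species_16s:<18} "
          f"{r.maldi_entry:<36} {r.maldi_score:<5} {r.category}")
```

prints

```
PF9-10.2.1     B. safensis        Bacillus safensis_FO36b^T            2.3   species_concordant
PF9-10.1.1     B. safensis        Bacillus safensis_FO36b^T            2.22  species_concordant
MER_TA_110.2   B. safensis        Bacillus safensis_FO36b^T            2.32  species_concordant
AMY_31.2       B. pumilus         Bacillus pumilus_DSM 27^T            2.33  species_concordant
AMY_17.1       B. pumilus         Bacillus australimaris_LMG_27697^T   2.32  maldi_confident_discordant
MER_178        B. australimaris   Bacillus safensis_FO36b^T            2.24  maldi_confident_discordant
MER_114.2      B. zhangzhouensis  Bacillus pumilus_DSM 27^T            2.36  maldi_confident_discordant
MSL_3001       B. pumilus         Bacillus australimaris_LMG_27697^T   2.19  potentially_novel
IN_293         B. australimaris   Bacillus safensis_FO36b^T            2.17  potentially_novel
V45.5          B. pumilus         Bacillus pumilus_DSM 27^T            2.03  potentially_novel
```

Four isolates are concordant between the two methods; three carry a
confident spectral identification that overrules the ambiguous 16S call
(the group members are ≥ 99.9 % identical in 16S); three score below 2.2
and are flagged as potentially novel species. `C.tabulate(records)`
returns the counts `{species_concordant: 4, maldi_confident_discordant:
3, potentially_novel: 3, ...}`.

The full pipeline — simulate a ground-truthed study, build and
self-validate the library, identify unknowns, compute the CCI matrix and
dendrogram, classify 16S queries and tabulate concordance — runs from the
shell:

```bash
spectyper all --out results/ --seed 7
```

and reports, among other things, the fraction of in-library unknowns
correctly identified at species level and the fraction of out-of-library
unknowns correctly left unidentified. Individual stages are available as
`spectyper simulate | preprocess | db-build | identify | cci | dendrogram
| 16s | concordance`.

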