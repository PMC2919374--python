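# ttdrank

Evidence-score synthesis of curated targeted-therapy literature, and
confidence-scored drug ranking against patient molecular profiles.

**Research use only.** Everything this package computes is a summary of
published evidence intended to generate hypotheses; none of it is suitable
for clinical decision making.

## The problem

Curated targeted-therapy databases collect one row per published study
finding: a molecule (in a molecular state such as `mut V600E`), a drug, the
kind of relationship studied (efficacy, synergism, toxicity), and the
hypothesis the study supports — favourable (+1), unfavourable (−1) or null
(0). The literature on any one molecule–drug pair is usually a mix of
conflicting findings from very different experimental systems, and because
such tables deliberately record *conclusions* rather than effect sizes, a
conventional meta-analysis cannot summarize them. `ttdrank` implements a
score-based alternative for researchers in precision oncology:

1. **Evidence score.** Each study is weighted by its experimental model.
   The seven model tiers (animal in vitro → animal in vivo → human in vitro
   → human xenograft → clinical study → randomized controlled trial →
   meta-analysis) form a doubling ladder starting at 6, so
   `model score = 6 · 2^tier`. A known sample size `n` adds a size score
   `n/10`, combined multiplicatively: `ES = model score · (1 + n/10)`.
2. **Score percentage.** Within a group of studies on the same
   (molecule, state, drug, relationship), `SP_i = ES_i / ΣES` is the
   fraction of the rated evidence supporting direction `i`.
3. **Prevalent hypothesis.** Treating evidence scores as binomial
   pseudo-counts, the Agresti–Coull corrected proportion is
   `SPc = (ES_i + z²/2)/(ΣES + z²)` with `SE = √(SPc(1−SPc)/(ΣES+z²))`.
   Direction `i` is *prevalent* when `SP_i > 0.5` **and** the 95% CI lower
   bound `SPc − z·SE` stays above 0.5 (a Z-test criterion is available as
   an alternative). Groups with a null or no prevalent hypothesis are
   eliminated from prediction; positive/negative groups become the drug's
   *informative molecules*.
4. **Overall score per drug.** For a patient profile, each informative
   molecule's SP gets a sign (+ sensitivity, − resistance, flipped when the
   patient carries the declared opposite state) and the signed SPs are
   pooled by inverse variance: `OS = Σ W_i·SP_i / Σ W_i`, `W_i = 1/V_i`,
   `V_i = SPc(1−SPc)`, `OV = 1/ΣW_i`, `SE = √OV`. An OS beyond ±0.5 whose
   CI clears the threshold classifies the profile sensitive/resistant;
   drugs are ranked by OS and compared pairwise with
   `Z = (OS_a − OS_b)/√(OV_a + OV_b)`.

A synthetic-corpus generator (known ground truth per group), responder
simulation (logistic link on OS) and validation metrics (Brier score with
Murphy decomposition, rank-based ROC/AUC) make the whole pipeline testable
without any external data.

## Worked example

```python
from ttdrank import (DrugRanker, EvidenceSummarizer, PatientProfile,
                     PatientProfileEntry, StatePairLexicon, parse_ttd_table)

records, issues = parse_ttd_table("""\
ID,Source,Molecule,Alias (molecule),State (molecule),Modifier,Alias (modifier),Relationship,Drug (therapy),Alias (drug),Model,H (hypothesis),Cases,Reference,Notes
1,melanoma specimen,BRAF,,mut V600E,,,efficacy:sensitivity,vemurafenib,PLX4032,randomized controlled trial,+1,337,Trial A,
2,melanoma specimen,BRAF,,mut V600E,,,efficacy:sensitivity,vemurafenib,PLX4032,human in vitro,+1,,Study B,
3,melanoma specimen,BRAF,,mut V600E,,,efficacy:resistance,vemurafenib,PLX4032,animal in vitro,-1,,Study C,
4,melanoma specimen,BRAF,,mut V600E,,,efficacy:resistance,dacarbazine,DTIC,human in vitro,-1,,Study D,
5,melanoma specimen,BRAF,,mut V600E,,,efficacy:resistance,dacarbazine,DTIC,human xenograft,-1,,Study E,
""")

frame = EvidenceSummarizer().fit(records).summary_frame()
print(frame[["molecule", "drug", "direction", "es", "sp", "ci_low", "prevalent"]])

lexicon = StatePairLexicon([("BRAF", "mut V600E", "wt")])
ranker = DrugRanker(lexicon=lexicon).fit(records)
profile = PatientProfile([PatientProfileEntry("BRAF", "mut V600E")])
for s in ranker.rank(profile).scores:
    print(f"{s.drug}: OS={s.os:+.4f} (CI {s.ci_low:+.4f}..{s.ci_high:+.4f}) "
          f"-> {s.classification}")
```

prints (abridged):

```
molecule        drug  direction     es       sp   ci_low prevalent
    braf vemurafenib          1 6686.4 0.999103 0.997994  positive
    braf vemurafenib         -1    6.0 0.000897 0.000360  positive
    braf dacarbazine         -1   72.0 1.000000 0.939315  negative
vemurafenib: OS=+0.9991 (CI +0.9317..+1.0000) -> sensitive
dacarbazine: OS=-1.0000 (CI -1.0000..-0.6921) -> resistant
```

The RCT with 337 patients carries `192 · (1 + 33.7) = 6662.4` evidence-score
units, so 99.9% of the rated vemurafenib evidence supports sensitivity and
the verdict is prevalent-positive; the patient carries the concordant state,
so vemurafenib ranks first as `sensitive` while the resistance evidence
pushes dacarbazine to a negative overall score.

The same pipeline is available from the shell:

```sh
ttd simulate --seed 5 --outdir sim            # synthetic corpus + truth table
ttd validate sim/corpus.csv
ttd summarize sim/corpus.csv --outdir out
ttd rank sim/corpus.csv --profile profile.csv --lexicon lexicon.csv
ttd metrics --scores scores.csv --outcomes outcomes.csv
```

Every run writes its outputs as CSV/JSON plus a manifest (inputs digests,
seeds, version) so identical inputs and seeds reproduce identical outputs.

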