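# credimeta

Credibility reappraisal of meta-analysed genetic associations, built for
the question pharmacoepidemiologists keep running into: a candidate-gene
meta-analysis reports a significant pooled odds ratio — how likely is it
to be a *true* association rather than a false positive, and how strong
is the cumulative epidemiological evidence behind it?

The package implements the full reappraisal toolchain used for published
meta-analyses of antiepileptic-drug (AED) resistance pharmacogenetics,
and ships the corresponding evidence tables so every stage runs without
downloads:

* **Bayesian false-positive metrics** from nothing but the pooled OR and
  its 95% CI —

  FPRP (Wacholder), with observed significance α = 2(1 − Φ(|Z|)),
  power 1 − β to detect a target OR, and prior π:

      FPRP = α(1 − π) / (α(1 − π) + (1 − β)π)

  BFDP (Wakefield), with V = SE², prior variance W = (ln OR₉₇.₅/1.96)²
  and prior odds of the null PO = (1 − π)/π:

      ABF  = √((V + W)/V) · exp(−Z²W / (2(V + W))),
      BFDP = ABF·PO / (ABF·PO + 1)

  A finding is *noteworthy* when FPRP < 0.2 (at every target OR) or
  BFDP < 0.8.  The SE is taken from the upper confidence limit,
  (ln UCI − ln OR)/1.96, the spreadsheet convention these metrics are
  conventionally computed with.

* **Venice criteria** — A/B/C grades for amount of evidence (total n),
  consistency (I²) and protection from bias (Egger p, small-effect
  rule), combined into Strong/Moderate/Weak.

* **AMSTAR-2** — overall confidence in a systematic review from its 16
  item responses, with the seven critical domains {2, 4, 7, 9, 11, 13, 15}.

* **Meta-analysis core** — inverse-variance fixed-effect and
  DerSimonian–Laird random-effects pooling, Q/I²/τ², the classic Egger
  regression test, and recovery of two-sided p-values from OR + CI.

* **Synthetic literatures** — per-study 2×2 tables under a true OR,
  between-study heterogeneity τ², and directional publication selection,
  for operating-characteristic studies of all of the above.

## Worked example

```python
from credimeta import assess, effect_from_ci

# ABCB1 rs2032582 G vs. A in Caucasian epilepsy patients: OR 0.45 (0.34-0.60)
res = assess(effect_from_ci(0.45, 0.34, 0.60))
print(round(res.fprp.fprp[(0.001, 1.5)], 3))   # 0.014
print(round(res.bfdp.bfdp[0.001], 3))          # 0.084
print(res.noteworthy_at(0.001))                # True
```

FPRP 0.014 says that, even granting only a 1-in-1000 prior probability
of a real association, fewer than 2% of such significant findings would
be false positives; BFDP 0.084 is the posterior probability of the null
itself.  Both sit far below their noteworthiness thresholds (0.2, 0.8),
so this association survives the strict prior.

Running the whole pipeline on the packaged evidence table
(`python examples/reappraise_comparisons.py`) prints all 23 significant
comparisons and ends with:

```
noteworthy at prior 0.001: 2 of 23
  ABCB1 rs2032582 G vs. A (Caucasian): Venice AAC/W
  ABCB1 rs2032582 GG vs. GA + AA (Caucasian): Venice BBC/W
comparisons surviving the joint credibility reading (noteworthy AND Venice not Weak): 0
```

— the two statistically robust contrasts are exactly the ones the
Venice criteria grade Weak for publication-bias concerns, so no
comparison survives the joint reading.  The other scripts in
`examples/` walk through the AMSTAR-2 appraisal, a single-estimate
credibility assessment, and publication-selection simulations.

A thin CLI mirrors the library:

```sh
credimeta assess --input comparisons.tsv --out report.tsv
credimeta simulate --config sim.yaml --out studies.tsv
credimeta pool --input studies.tsv --model random --egger
credimeta amstar --input amstar.tsv --out ratings.tsv
```

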