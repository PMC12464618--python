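"""Full reappraisal of the packaged AED-resistance comparisons.

Runs the pipeline on the 23 significant pooled comparisons (7 SNPs in 4
genes) compiled from published meta-analyses: FPRP/BFDP at priors
0.05/0.001, Venice grades, and the joint credibility flag.  The
headline: only the two ABCB1 rs2032582 contrasts in Caucasian patients
are noteworthy at the strict prior, and both carry a Weak Venice grade
(publication-bias signal), so nothing survives the joint reading.
"""

from credimeta import load_aed_comparisons, run
from credimeta.pipeline import report_frame

records = load_aed_comparisons()
report = run(records)
df = report_frame(report)

print(df[["variant", "contrast", "subgroup", "or_point",
          "fprp_or1.5_pi0.001", "bfdp_pi0.001",
          "venice_code", "venice_label"]].to_string(index=False))

noteworthy = [r for r in report.rows if r.noteworthy[0.001]]
print(f"\nnoteworthy at prior 0.001: {len(noteworthy)} of {len(report.rows)}")
for r in noteworthy:
    print(f"  {r.record.gene} {r.record.variant} {r.record.contrast} "
          f"({r.record.subgroup}): Venice {r.venice.code}/{r.venice.label}")
print("comparisons surviving the joint credibility reading "
      f"(noteworthy AND Venice not Weak): "
      f"{sum(r.credible_noteworthy for r in report.rows)}")
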