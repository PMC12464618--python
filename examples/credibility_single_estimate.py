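"""Credibility of a single pooled estimate.

Takes one pooled OR with its 95% CI (the ABCB1 rs2032582 G vs. A
comparison in Caucasian epilepsy patients, OR 0.45, 0.34-0.60) and
computes the FPRP grid and BFDP.  Small values mean the significant
finding is unlikely to be a false positive at that prior.
"""

from credimeta import PriorSpec, assess, effect_from_ci

effect = effect_from_ci(0.45, 0.34, 0.60)
spec = PriorSpec()  # priors 0.05/0.001, detectable ORs 1.5/2.0
res = assess(effect, spec)

print(f"theta = {effect.theta:+.4f}  SE = {effect.se:.4f}  "
      f"|Z| = {abs(effect.z):.2f}  alpha = {effect.alpha:.2e}\n")
print("FPRP (prior x detectable OR):")
for (pi, target), value in sorted(res.fprp.fprp.items(), reverse=True):
    star = " *" if res.fprp.noteworthy[(pi, target)] else ""
    print(f"  pi={pi:<6g} OR {target}: {value:.3f}{star}")
print("\nBFDP (prior):")
for pi, value in res.bfdp.bfdp.items():
    star = " *" if res.bfdp.noteworthy[pi] else ""
    print(f"  pi={pi:<6g}: {value:.3f}{star}")
print(f"\nnoteworthy at the strict prior 0.001: {res.noteworthy_at(0.001)}")
print("(* = below the noteworthiness threshold, 0.2 for FPRP, 0.8 for BFDP)")
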