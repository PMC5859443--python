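"""Exact binomial tests of Mendelian methylation inheritance.

A backcross of a fully methylated F1 to the unmethylated recurrent
parent should yield highly methylated plants at rate 1/2; an F2 should
contain 1/4 unmethylated plants.  One-sided exact binomial tails
quantify distortions towards methylation gain.
"""

from paraseg.segregation import SegregationObservation, test_bc1, test_f2

bc1 = test_bc1(SegregationObservation("BC1", n_total=26, n_in_class=18,
                                      tested_class="high"))
print(f"BC1: {bc1.observation.n_in_class}/{bc1.observation.n_total} high, "
      f"p = {bc1.p_value:.5f} (one-sided, p0 = {bc1.null.p0})"
      + (f" -> {bc1.note}" if bc1.flagged else ""))

f2 = test_f2(SegregationObservation("F2", n_total=33, n_in_class=3,
                                    tested_class="low"))
print(f"F2:  {f2.observation.n_in_class}/{f2.observation.n_total} low,  "
      f"p = {f2.p_value:.3f} (one-sided, p0 = {f2.null.p0})"
      + (f" -> {f2.note}" if f2.flagged else ""))
# Small p-values mean the progeny are more methylated than Mendelian
# segregation of a stable epiallele allows: a paramutation-like signal.
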