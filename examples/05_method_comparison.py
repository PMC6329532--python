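"""Compare coupling methods with the Wilcoxon signed-rank test.

Each method is scored on the same thirty benchmark analyses (bundled
published s-score columns for CCMpred, EVcouplings, GaussDCA and PSICOV).
The paired Wilcoxon test on the per-analysis scores asks whether one method
tends to score higher than another; Z > 0 favours the first-named method.
(Scores are normally normalised by each analysis' array length L before
testing; the bundled columns lack per-analysis L, so they are compared
unnormalised here, which changes the weighting of large domains.)
"""

from starc import compare_methods
from starc.benchmarks import SUPERFAMILY_S

for res in compare_methods({k: v for k, v in SUPERFAMILY_S.items()}):
    print(res)

print(
    "\nLarge positive Z with small p: the first method outscores the second"
    "\nconsistently across analyses, not just on average."
)
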