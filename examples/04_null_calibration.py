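"""Check that the corrected p-value is honest on shuffled null arrays.

Shuffling a binary ranked array destroys any association between coupling
order and contacts while keeping L and D.  If the statistic is calibrated,
the fraction of null s-scores exceeding S should be 10**-S: the empirical
curve S-hat(S) should track the diagonal within binomial error.
"""

from starc import calibration_curve

curve = calibration_curve(L=2000, D=100, n_rep=5000, seed=0,
                          grid=[2.0, 2.5, 3.0])
print(curve.to_tsv())
print("within two-SD band:", list(curve.within_band()))
print(
    "\nS_hat close to S means a reported s-score of, say, 3 really does"
    "\ncorrespond to a one-in-a-thousand event under the null."
)
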