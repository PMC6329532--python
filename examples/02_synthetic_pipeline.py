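"""Full pipeline on a synthetic fold with planted coupling signal.

A 60-residue chain is generated by a confined persistent random walk;
pairs closer than 5 Angstrom (with at least 5 intervening residues) are the
planted contacts, and coupling scores are theta * 1[contact] + N(0, 1).
With theta = 4 the contacts concentrate at the top of the score-ordered
array and S should be large; with theta = 0 the scores carry no signal and
S should hover near zero.
"""

from starc import make_fixture, score_fixture

for theta in (4.0, 0.0):
    fx = make_fixture(n_res=60, theta=theta, seed=11)
    rep = score_fixture(fx)
    print(
        f"theta={theta:3.1f}: L={rep.L} pairs, D={rep.D} contacts, "
        f"X={rep.X}, d={rep.d}, R={rep.R}, S={rep.S:.2f}"
    )

print(
    "\nS is -log10 of the corrected joint p-value: tens of orders of"
    "\nmagnitude for the planted signal, near zero for pure noise."
)
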