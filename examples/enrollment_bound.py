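"""Daugman-style enrollment capacity: how many classes before collisions?

With imposter distances Erlang(K, P)-distributed, the false match rate at a
distance threshold tau is the imposter cumulative FMR(tau); enrolling M
classes keeps the collision probability below delta iff
M <= ln(1 - delta) / ln(1 - FMR(tau)).
"""

from iriscap import ImposterFit, enrollment_table

fit = ImposterFit(K=4, P=252.0, sse=0.0)  # relative-entropy imposter fit
table = enrollment_table(
    fit, tau_grid=[1, 10, 50, 100], delta_grid=[0.5, 0.1, 0.01, 0.001],
    fmr_mode="unit_grid",
)
print(table.to_string(index=False))
print(
    "\ntau is the minimum codeword distance between distinct classes (a data"
    " quality floor); delta the tolerated chance that a new class collides"
    " with any enrolled one.  Tight quality (small tau) and loose delta both"
    " enlarge the supportable population M_reported."
)
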