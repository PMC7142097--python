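"""Transmission statistics: is NUMT inheritance autosomal?

A heterozygous father transmits an autosomal insertion to each child with
probability 1/2.  The observed transmission proportion with an exact
Clopper-Pearson interval tests consistency with Mendelian expectation.
"""

from meganumt import clopper_pearson_ci, transmission_summary

# 10 of 17 father-offspring pairs transmitted the rare NUMT
pairs = [(f"father{i}", f"child{i}", i < 10) for i in range(17)]
summary = transmission_summary(pairs)
print(
    f"transmitted {summary.n_transmitted}/{summary.n_pairs} = "
    f"{summary.proportion:.1f}% "
    f"(95% CI {summary.ci_low:.1f}-{summary.ci_high:.1f}%)"
)
print("the interval comfortably contains 50% -> consistent with autosomal transmission")

# the exact interval at the boundaries
print("0/17 transmitted:", tuple(round(x, 3) for x in clopper_pearson_ci(0, 17)))
print("17/17 transmitted:", tuple(round(x, 3) for x in clopper_pearson_ci(17, 17)))
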