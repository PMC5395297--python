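"""Genetic interaction in fertility under the multiplicative null.

If two genes do not interact, the double mutant's expected brood is
(single A brood x single B brood) / wild-type brood. Broods are simulated
for a synthetic-sterile pair (double mutant at 30% of the multiplicative
expectation) and for a non-interacting pair, and both are tested one-sided
for broods below expectation.
"""

from hetchrom.interactions import interaction_test
from hetchrom.synth import make_broods

for model in ("multiplicative", "sub_multiplicative"):
    table, truth = make_broods(
        wt_mean=250, a_effect=0.6, b_effect=0.6,
        interaction=model, sub_fraction=0.3, n_per_genotype=12, seed=1,
    )
    res = interaction_test(table, propagate_uncertainty=True)
    print(f"{model}:")
    print(f"  expected double brood {res.expected_double:.1f}, "
          f"observed {res.observed_mean:.1f}, one-sided p = {res.p_value:.3g}")

print(
    "\nUnder the multiplicative (no-interaction) model p stays large; the\n"
    "sub-multiplicative pair shows a brood far below expectation - the\n"
    "synthetic-sterility signature of redundant gene function."
)
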