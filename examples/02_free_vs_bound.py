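"""Compare the conformer ensembles of a free and an RNA-bound conjugate.

Emulates the hallmark population shift of contact-quenched fluorophore
probes on aptamer binding: the xanthene-stacked class collapses while the
non-contact class grows. Prints per-class deltas with two-proportion z
statistics.
"""

from fqens import run_comparison, run_ensemble_analysis
from fqens.synthetic import (
    BOUND_FRACTIONS,
    EnsembleSpec,
    FREE_FRACTIONS,
    generate_ensemble,
)

free_models, _, cfg = generate_ensemble(EnsembleSpec(100, FREE_FRACTIONS, 0.05, seed=7))
bound_models, _, _ = generate_ensemble(EnsembleSpec(100, BOUND_FRACTIONS, 0.05, seed=8))

comparison = run_comparison(
    run_ensemble_analysis(free_models, cfg),
    run_ensemble_analysis(bound_models, cfg),
)

print(f"{'class':<18}{'free':>7}{'bound':>7}{'delta':>8}{'z':>8}{'p':>10}")
for d in comparison.deltas:
    print(f"{d.label:<18}{d.fraction_a:>7.2f}{d.fraction_b:>7.2f}"
          f"{d.delta:>+8.2f}{d.z_statistic:>8.2f}{d.p_value:>10.2g}")
print()
print("A large negative StackX delta with |z| >> 2 marks the loss of")
print("quencher-on-xanthene stacking on binding; the matching non-contact")
print("gain shows the quencher being pushed off the fluorophore.")
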